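"""Network arm: group spatial ICA and its downstream analyses.

Temporally concatenated multi-subject BOLD is decomposed into K spatially
independent component maps (fixed-point negentropy ICA with PCA whitening
and symmetric decorrelation; map sign fixed by positive skewness).  The
decomposition is validated by split-half matching (components with
|r|_max >= 0.7 against the other subsample are replicable; 0.6-0.7 flagged
for inspection), characterized against resting-state network templates
(|r| > 0.1 lenient, > 0.2 stringent), and carried into subject space by
stage-1 dual regression.  Per-component task responsivity (standardized
beta difference, pictures minus geometrical figures) is then related to
recall performance with Bonferroni correction over the K components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.mixture import GaussianMixture

from .design import DesignMatrix, highpass_basis
from .glm import BoldRun
from .group import bonferroni_threshold

__all__ = [
    "ICASet",
    "MatchTable",
    "SubjectTimecourses",
    "concat_and_decompose",
    "threshold_map",
    "match_decompositions",
    "dual_regression_stage1",
    "network_responsivity",
    "network_behavior_models",
    "rsn_similarity",
]

REPLICABLE_RMAX = 0.7
INSPECT_RMAX = 0.6
RSN_LENIENT = 0.1
RSN_STRINGENT = 0.2


@dataclass
class ICASet:
    """K spatial component maps plus the group mixing matrix.

    ``maps`` is voxels x K over the in-mask voxels (``np.flatnonzero(mask)``
    order); ``mixing`` is concatenated-time x K.  Map sign is fixed so each
    component's skewness is positive.
    """

    maps: np.ndarray
    mixing: np.ndarray
    mask: np.ndarray
    seed: int
    subsample_id: str = ""

    @property
    def k(self) -> int:
        return self.maps.shape[1]

    def map_volume(self, j: int) -> np.ndarray:
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.maps[:, j]
        return vol


def _concatenate_normalized(
    runs: list[BoldRun],
    mask: np.ndarray,
    var_norm: bool = True,
    highpass_cutoff: float | None = 128.0,
) -> np.ndarray:
    """MELODIC-style preprocessing: per subject, de-mean each voxel in time
    and remove low-frequency drift (discrete-cosine high-pass, default
    128 s cutoff, matching the first-level filter); after concatenation,
    divide by the voxel-wise SD (``var_norm=False`` skips the SD division
    for analyses of amplitude structure)."""
    blocks = []
    flat_mask = mask.ravel()
    for run in runs:
        y = run.data.reshape(-1, run.n_volumes)[flat_mask].T.astype(float)
        y = y - y.mean(axis=0)
        if highpass_cutoff is not None:
            dct = highpass_basis(run.n_volumes, run.tr, highpass_cutoff)
            if dct.shape[1]:
                y = y - dct @ (dct.T @ y)  # orthonormal basis projection
        blocks.append(y)
    x = np.concatenate(blocks, axis=0)  # total-time x voxels
    sd = x.std(axis=0)
    if (sd == 0).any():
        raise ValueError("degenerate (constant) voxels inside the mask")
    if var_norm:
        x = x / sd
    # temporal de-meaning already zeroes each voxel's mean (and hence the
    # grand mean); per-volume spatial de-meaning is deliberately omitted as
    # it couples otherwise independent spatial sources
    return x


def concat_and_decompose(
    runs: list[BoldRun],
    k: int,
    seed: int = 0,
    mask: np.ndarray | None = None,
    subsample_id: str = "",
    max_iter: int = 2000,
    var_norm: bool = True,
    highpass_cutoff: float | None = 128.0,
) -> ICASet:
    """Group spatial ICA on temporally concatenated runs.

    The normalized concatenated matrix is PCA-reduced to K and unmixed by
    FastICA (logcosh negentropy contrast, parallel/symmetric decorrelation),
    treating voxels as samples so the estimated sources are spatial maps.
    Deterministic given the seed.
    """
    if not runs:
        raise ValueError("no runs given")
    if mask is None:
        mask = runs[0].mask
    if any(r.mask.shape != mask.shape for r in runs):
        raise ValueError("runs must share a common mask shape")
    x = _concatenate_normalized(
        runs, mask, var_norm=var_norm, highpass_cutoff=highpass_cutoff
    )
    total_t, n_vox = x.shape
    if k >= total_t or k > n_vox:
        raise ValueError("K must be below the concatenated time points and voxels")
    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional convergence chatter
        sources = ica.fit_transform(x.T)  # voxels x K spatial maps
    mixing = ica.mixing_  # total-time x K
    sign = np.where(stats.skew(sources, axis=0) < 0, -1.0, 1.0)
    return ICASet(
        maps=sources * sign,
        mixing=mixing * sign,
        mask=np.asarray(mask, bool),
        seed=seed,
        subsample_id=subsample_id,
    )


def threshold_map(
    component_map: np.ndarray, method: str = "zscore", level: float = 3.0
) -> np.ndarray:
    """Retain the voxels that load on a component.

    ``zscore``: keep |z| > level (default 3) after standardizing the map.
    ``mixture``: fit a two-component Gaussian mixture to the loadings and
    keep voxels whose posterior for the wider (signal) component exceeds
    0.5; falls back to the z-score rule with a warning if the fit fails.
    Returns a boolean array of the map's shape.
    """
    m = np.asarray(component_map, dtype=float).ravel()
    if not np.isfinite(m).all():
        raise ValueError("component map must be finite")
    shape = np.asarray(component_map).shape
    if np.ptp(m) == 0.0:
        return np.zeros(shape, dtype=bool)
    if method == "mixture":
        try:
            gm = GaussianMixture(n_components=2, random_state=0, max_iter=200)
            gm.fit(m[:, None])
            if not gm.converged_:
                raise ValueError("mixture fit did not converge")
            # the null mode sits near zero; signal has the larger |mean|
            signal = int(np.argmax(np.abs(gm.means_.ravel())))
            post = gm.predict_proba(m[:, None])[:, signal]
            return (post > 0.5).reshape(shape)
        except Exception as exc:  # pragma: no cover - rare degenerate fits
            warnings.warn(f"mixture thresholding failed ({exc}); using zscore")
            method = "zscore"
    if method == "zscore":
        z = (m - m.mean()) / m.std()
        return (np.abs(z) > level).reshape(shape)
    raise ValueError(f"unknown threshold method {method!r}")


@dataclass
class MatchTable:
    """Cross-decomposition |r| matrix and per-component replicability flags."""

    r_abs: np.ndarray  # K_a x K_b absolute Pearson correlations
    r_max: np.ndarray  # per component of a
    best_match: np.ndarray  # argmax component of b
    status: list[str]  # replicable / inspect / not_replicable

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(len(self.r_max)),
                "r_max": self.r_max,
                "best_match": self.best_match,
                "status": self.status,
            }
        )


def match_decompositions(a: ICASet, b: ICASet) -> MatchTable:
    """Split-half component matching on unthresholded voxel loadings.

    All pairwise Pearson |r| between the two map sets over in-mask voxels;
    r_max per component of ``a`` regardless of how many pairs pass.  Flags:
    replicable iff |r|_max >= 0.7, inspect iff 0.6 <= |r|_max < 0.7.
    """
    if a.mask.shape != b.mask.shape or not np.array_equal(a.mask, b.mask):
        raise ValueError("decompositions must share the same mask")
    za = (a.maps - a.maps.mean(axis=0)) / a.maps.std(axis=0)
    zb = (b.maps - b.maps.mean(axis=0)) / b.maps.std(axis=0)
    r = np.abs(za.T @ zb / za.shape[0])
    r_max = r.max(axis=1)
    best = r.argmax(axis=1)
    status = [
        "replicable"
        if rm >= REPLICABLE_RMAX
        else ("inspect" if rm >= INSPECT_RMAX else "not_replicable")
        for rm in r_max
    ]
    return MatchTable(r_abs=r, r_max=r_max, best_match=best, status=status)


@dataclass
class SubjectTimecourses:
    """K x T component time series for one subject (dual-regression stage 1)."""

    subject_id: str | int | None
    timecourses: np.ndarray  # K x T

    @property
    def k(self) -> int:
        return self.timecourses.shape[0]


def dual_regression_stage1(
    run: BoldRun, ica: ICASet, condition_limit: float = 1e8
) -> SubjectTimecourses:
    """Regress the group maps into one subject's 4-D data.

    For every volume, the voxel vector is modeled by a multiple regression
    on all K spatial maps jointly (plus an intercept absorbing the volume
    mean); the per-map coefficient series are the subject-specific
    component time courses.  A joint solve -- not per-map projection -- so
    correlated maps are handled exactly.
    """
    if run.mask.shape != ica.mask.shape:
        raise ValueError("run and ICA masks do not match")
    y = run.data.reshape(-1, run.n_volumes)[ica.mask.ravel()].astype(float)
    design = np.column_stack([ica.maps, np.ones(ica.maps.shape[0])])
    if np.linalg.cond(design) > condition_limit:
        raise ValueError("spatial maps are collinear (condition number guard)")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return SubjectTimecourses(subject_id=run.subject_id, timecourses=coef[:-1])


def _standardized_betas(y: np.ndarray, x: DesignMatrix) -> dict[str, float]:
    xm = x.values
    beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
    sd_y = y.std()
    if sd_y == 0:
        return {name: 0.0 for name in x.column_names}
    sd_x = xm.std(axis=0)
    return {
        name: float(beta[j] * sd_x[j] / sd_y)
        for j, name in enumerate(x.column_names)
    }


def network_responsivity(
    tc: SubjectTimecourses,
    x: DesignMatrix,
    task_column: str = "pictures",
    control_column: str = "figures",
) -> pd.DataFrame:
    """Task-related functional responsivity per component.

    Each component time course is regressed on the first-level design
    (picture, figure, primacy/recency, rating, button and motion columns);
    responsivity = standardized beta(pictures) - standardized beta(figures).
    """
    if tc.timecourses.shape[1] != x.n_volumes:
        raise ValueError("time course length does not match the design")
    rows = []
    for j in range(tc.k):
        betas = _standardized_betas(tc.timecourses[j], x)
        rows.append(
            {
                "subject_id": tc.subject_id,
                "component": j,
                "beta_task": betas[task_column],
                "beta_control": betas[control_column],
                "responsivity": betas[task_column] - betas[control_column],
            }
        )
    return pd.DataFrame(rows)


def network_behavior_models(
    responsivity: pd.DataFrame,
    phenotype: pd.DataFrame,
    alpha: float = 0.05,
    covariates: tuple[str, ...] = ("age", "sex", "batch_mr", "room"),
) -> pd.DataFrame:
    """Per-component linear models of recall on responsivity.

    recall_count ~ responsivity + age + sex + batch, two-sided p for the
    responsivity slope, significance at the Bonferroni level alpha / K, and
    the R^2 increment of the responsivity term over the covariate-only
    model.
    """
    merged = responsivity.merge(phenotype, on="subject_id", validate="many_to_one")
    k = merged["component"].nunique()
    thr = bonferroni_threshold(alpha, k)
    rows = []
    for comp, grp in merged.groupby("component"):
        y = grp["recall_count"].to_numpy(dtype=float)
        n = len(grp)
        cov_cols = [np.ones(n)]
        for cov in covariates:
            series = grp[cov]
            if series.dtype.kind in "if":
                cov_cols.append(series.to_numpy(dtype=float))
            else:
                for level in sorted(series.astype(str).unique())[1:]:
                    cov_cols.append((series.astype(str) == level).to_numpy(float))
        z = np.column_stack(cov_cols)
        x = np.column_stack([grp["responsivity"].to_numpy(dtype=float), z])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("collinear covariates in network-behavior model")
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        dof = n - x.shape[1]
        sigma2 = resid @ resid / dof
        cvar = np.linalg.inv(x.T @ x)[0, 0]
        se = np.sqrt(sigma2 * cvar)
        t = beta[0] / se if se > 0 else np.sign(beta[0]) * np.inf
        p = float(2.0 * stats.t.sf(abs(t), dof))
        # R^2 increment over covariates alone
        beta_z, *_ = np.linalg.lstsq(z, y, rcond=None)
        rss_red = float(((y - z @ beta_z) ** 2).sum())
        rss_full = float((resid**2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        r2_inc = (rss_red - rss_full) / tss if tss > 0 else 0.0
        rows.append(
            {
                "component": comp,
                "slope": float(beta[0]),
                "t": float(t),
                "p": p,
                "significant": p < thr,
                "r2_increment": r2_inc,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_alpha"] = thr
    return out


def rsn_similarity(
    ica: ICASet, templates: np.ndarray, template_names: list[str] | None = None
) -> pd.DataFrame:
    """Spatial correlation of each component with resting-state templates.

    ``templates`` is n_templates x X x Y x Z (or n_templates x voxels on
    the ICA mask).  Reports, per component, the best-matching template and
    the number of templates passing the lenient (|r| > 0.1) and stringent
    (|r| > 0.2) thresholds.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.ndim == 4:
        if templates.shape[1:] != ica.mask.shape:
            raise ValueError("templates are not on the analysis grid")
        tmat = templates.reshape(templates.shape[0], -1)[:, ica.mask.ravel()]
    else:
        tmat = templates
        if tmat.shape[1] != ica.maps.shape[0]:
            raise ValueError("templates are not on the analysis mask")
    if template_names is None:
        template_names = [f"rsn_{i}" for i in range(tmat.shape[0])]
    za = (ica.maps - ica.maps.mean(axis=0)) / ica.maps.std(axis=0)
    zt = (tmat - tmat.mean(axis=1, keepdims=True)) / tmat.std(axis=1, keepdims=True)
    r = za.T @ zt.T / za.shape[0]  # K x n_templates, signed
    rows = []
    for j in range(ica.k):
        rj = np.abs(r[j])
        rows.append(
            {
                "component": j,
                "best_template": template_names[int(rj.argmax())],
                "best_r": float(r[j][int(rj.argmax())]),
                "n_lenient": int((rj > RSN_LENIENT).sum()),
                "n_stringent": int((rj > RSN_STRINGENT).sum()),
            }
        )
    return pd.DataFrame(rows)
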