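"""First-level design construction.

Builds the time x regressor matrix for a single encoding run: task events
(boxcars or stick functions) convolved with a canonical double-gamma
hemodynamic response, parametric modulators with serial orthogonalization
(each modulator column is residualized against the unmodulated column and
all earlier modulators, in the stated order), a discrete-cosine high-pass
basis (default cutoff 128 s), unconvolved motion nuisance series, and an
intercept.

Regressors are built on a fine microtime grid (default 0.1 s), convolved
there, and sampled at the volume acquisition times ``t = k * TR``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HRFSpec",
    "DesignMatrix",
    "canonical_hrf",
    "build_task_regressor",
    "add_parametric_modulators",
    "highpass_basis",
    "build_first_level_design",
]


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response parameters.

    The kernel is the difference of two gamma densities -- a positive peak
    (delay ~6 s) minus a scaled undershoot (delay ~16 s) -- sampled on the
    microtime grid and normalized to unit peak.
    """

    peak_delay: float = 6.0  # s
    undershoot_delay: float = 16.0  # s
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0  # s
    microtime_dt: float = 0.1  # s

    def __post_init__(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("HRF dispersions must be positive")
        if self.kernel_length < self.undershoot_delay:
            raise ValueError("kernel_length must cover the undershoot delay")
        if self.microtime_dt <= 0:
            raise ValueError("microtime_dt must be positive")


def canonical_hrf(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Sample the canonical HRF kernel on the microtime grid.

    Returns the kernel values at ``t = 0, dt, 2 dt, ..., kernel_length``,
    peak-normalized so the maximum is exactly 1.
    """
    t = np.arange(0.0, spec.kernel_length + spec.microtime_dt / 2, spec.microtime_dt)
    peak = gamma_dist.pdf(
        t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = gamma_dist.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    kernel = peak - under / spec.peak_undershoot_ratio
    return kernel / kernel.max()


def _microtime_neural(
    onsets: np.ndarray,
    durations: np.ndarray | None,
    amplitudes: np.ndarray | None,
    kind: str,
    run_length: float,
    dt: float,
) -> np.ndarray:
    """Stimulus function on the microtime grid (boxcar or delta train)."""
    n = int(np.ceil(run_length / dt))
    u = np.zeros(n)
    onsets = np.asarray(onsets, dtype=float)
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    if kind == "delta":
        for onset, amp in zip(onsets, amplitudes):
            idx = int(round(onset / dt))
            if 0 <= idx < n:
                u[idx] += amp / dt  # unit-area impulse
    elif kind == "epoch":
        if durations is None:
            raise ValueError("epoch regressors need durations")
        durations = np.asarray(durations, dtype=float)
        for onset, dur, amp in zip(onsets, durations, amplitudes):
            i0 = int(round(onset / dt))
            i1 = int(round((onset + dur) / dt))
            if i1 > n:
                warnings.warn(
                    f"event at {onset:.2f}s extends past run end; truncated",
                    stacklevel=3,
                )
                i1 = n
            u[max(i0, 0) : i1] += amp
    else:
        raise ValueError(f"unknown regressor kind {kind!r}")
    return u


def build_task_regressor(
    onsets: Sequence[float],
    durations: Sequence[float] | None,
    n_volumes: int,
    tr: float,
    kind: str = "epoch",
    hrf: HRFSpec = HRFSpec(),
    amplitudes: Sequence[float] | None = None,
) -> np.ndarray:
    """One HRF-convolved task column sampled at the volume times.

    ``kind`` is ``"epoch"`` (boxcar over each event's duration; pictures and
    rating scales) or ``"delta"`` (stick function; button presses).  Events
    extending past the run end are truncated with a warning.  An empty event
    list yields a zero column.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        return np.zeros(n_volumes)
    if (onsets < 0).any() or (onsets >= n_volumes * tr).any():
        raise ValueError("event onsets must lie within the run")
    dt = hrf.microtime_dt
    run_length = n_volumes * tr
    u = _microtime_neural(
        onsets,
        None if durations is None else np.asarray(durations, float),
        None if amplitudes is None else np.asarray(amplitudes, float),
        kind,
        run_length,
        dt,
    )
    kernel = canonical_hrf(hrf)
    conv = np.convolve(u, kernel)[: len(u)] * dt
    sample_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    sample_idx = np.minimum(sample_idx, len(conv) - 1)
    return conv[sample_idx]


def add_parametric_modulators(
    onsets: Sequence[float],
    durations: Sequence[float],
    modulators: dict[str, Sequence[float]],
    n_volumes: int,
    tr: float,
    hrf: HRFSpec = HRFSpec(),
    base_column: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Parametric-modulator columns with serial orthogonalization.

    Each modulator value series is mean-centered over events, multiplies the
    event boxcar, and is convolved with the HRF; the convolved column is then
    residualized (ordinary least squares) against the unmodulated column and
    every earlier modulator column, in the given order.  A modulator that is
    constant over events yields a zero column with a warning.

    ``modulators`` preserves insertion order; e.g. memorability first, the
    remembered indicator second.
    """
    onsets = np.asarray(onsets, dtype=float)
    if base_column is None:
        base_column = build_task_regressor(
            onsets, durations, n_volumes, tr, kind="epoch", hrf=hrf
        )
    predecessors = [base_column]
    out: dict[str, np.ndarray] = {}
    for name, values in modulators.items():
        values = np.asarray(values, dtype=float)
        if values.shape[0] != onsets.shape[0]:
            raise ValueError(f"modulator {name!r}: one value per event required")
        centered = values - values.mean()
        if np.allclose(centered, 0.0):
            warnings.warn(
                f"modulator {name!r} is constant over events; zero column",
                stacklevel=2,
            )
            out[name] = np.zeros(n_volumes)
            continue
        col = build_task_regressor(
            onsets,
            durations,
            n_volumes,
            tr,
            kind="epoch",
            hrf=hrf,
            amplitudes=centered,
        )
        pred = np.column_stack(predecessors)
        coef, *_ = np.linalg.lstsq(pred, col, rcond=None)
        resid = col - pred @ coef
        out[name] = resid
        predecessors.append(resid)
    return out


def highpass_basis(n_volumes: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass filter basis (nuisance columns).

    Returns the DCT components with period longer than ``cutoff`` seconds,
    excluding the constant: ``K = floor(2 * T * tr / cutoff)`` columns, each
    unit-norm, mutually orthogonal.  ``cutoff`` must exceed ``2 * tr``.
    """
    if cutoff <= 2 * tr:
        raise ValueError("high-pass cutoff must exceed 2 * TR")
    n_basis = int(np.floor(2.0 * n_volumes * tr / cutoff))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes)) for k in range(1, n_basis + 1)
    ]
    if not cols:
        return np.zeros((n_volumes, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


@dataclass
class DesignMatrix:
    """Time x regressor matrix with named, role-tagged columns.

    ``column_roles`` maps each name to one of ``task``, ``modulator``,
    ``nuisance``, ``filter``, ``intercept``.  Exactly one intercept column
    is present.
    """

    values: np.ndarray
    column_names: list[str]
    column_roles: dict[str, str]
    tr: float
    highpass_cutoff: float = 128.0
    hrf: HRFSpec = field(default_factory=HRFSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("one name per column required")
        n_icpt = sum(1 for r in self.column_roles.values() if r == "intercept")
        if n_icpt != 1:
            raise ValueError("design must contain exactly one intercept")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV with a JSON sidecar of roles/metadata."""
        path = Path(path)
        pd.DataFrame(self.values, columns=self.column_names).to_csv(
            path, sep="\t", index=False
        )
        sidecar = {
            "tr": self.tr,
            "highpass_cutoff": self.highpass_cutoff,
            "column_roles": self.column_roles,
            "hrf": {
                "peak_delay": self.hrf.peak_delay,
                "undershoot_delay": self.hrf.undershoot_delay,
                "peak_dispersion": self.hrf.peak_dispersion,
                "undershoot_dispersion": self.hrf.undershoot_dispersion,
                "peak_undershoot_ratio": self.hrf.peak_undershoot_ratio,
                "kernel_length": self.hrf.kernel_length,
                "microtime_dt": self.hrf.microtime_dt,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


# -- first-level model layouts -------------------------------------------------
#
# Three regressor layouts are used downstream, mirroring the three first-level
# analyses: (1) "subsequent_memory" splits target pictures into later-recalled
# vs later-not-recalled boxcars; (2) "memorability_pm" keeps one unmodulated
# target-picture regressor plus serially orthogonalized parametric modulators
# (norm value first, remembered indicator second); (3) "picture_encoding"
# models target pictures vs scrambled geometrical figures.  All layouts share
# the rating-scale epochs, button-press deltas, six unconvolved motion series,
# the DCT filter block and the intercept.

_SCHEMES = ("subsequent_memory", "memorability_pm", "arousal_pm", "picture_encoding")


def build_first_level_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    scheme: str = "picture_encoding",
    motion: np.ndarray | None = None,
    hrf: HRFSpec = HRFSpec(),
    highpass_cutoff: float = 128.0,
) -> DesignMatrix:
    """Assemble a full first-level design for one of the model layouts.

    ``events`` is a BIDS-style table with columns onset, duration, trial_type
    (target / scrambled / primacy / recency / rating / button) and, for
    targets, memorability, arousal and remembered columns.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")

    def sel(ttype: str) -> pd.DataFrame:
        return events[events["trial_type"] == ttype]

    def task_col(sub: pd.DataFrame, kind: str = "epoch") -> np.ndarray:
        return build_task_regressor(
            sub["onset"].to_numpy(),
            sub["duration"].to_numpy() if kind == "epoch" else None,
            n_volumes,
            tr,
            kind=kind,
            hrf=hrf,
        )

    columns: list[np.ndarray] = []
    names: list[str] = []
    roles: dict[str, str] = {}

    def add(name: str, col: np.ndarray, role: str) -> None:
        columns.append(col)
        names.append(name)
        roles[name] = role

    targets = sel("target")
    edge = events[events["trial_type"].isin(("primacy", "recency"))]

    if scheme == "subsequent_memory":
        remembered = targets[targets["remembered"] == 1]
        forgotten = targets[targets["remembered"] == 0]
        add("recalled", task_col(remembered), "task")
        add("not_recalled", task_col(forgotten), "task")
        if len(edge):
            add("primacy_recency", task_col(edge), "task")
    elif scheme in ("memorability_pm", "arousal_pm"):
        base = task_col(targets)
        add("pictures", base, "task")
        first = "memorability" if scheme == "memorability_pm" else "arousal"
        pm_cols = add_parametric_modulators(
            targets["onset"].to_numpy(),
            targets["duration"].to_numpy(),
            {
                f"pm_{first}": targets[first].to_numpy(dtype=float),
                "pm_memory": targets["remembered"].to_numpy(dtype=float),
            },
            n_volumes,
            tr,
            hrf=hrf,
            base_column=base,
        )
        for name, col in pm_cols.items():
            if not col.any():  # constant modulator; keep the design full rank
                continue
            add(name, col, "modulator")
        scram = sel("scrambled")
        if len(scram):
            add("figures", task_col(scram), "task")
        if len(edge):
            add("primacy_recency", task_col(edge), "task")
    else:  # picture_encoding
        add("pictures", task_col(targets), "task")
        scram = sel("scrambled")
        if len(scram):
            add("figures", task_col(scram), "task")
        if len(edge):
            add("primacy_recency", task_col(edge), "task")

    ratings = sel("rating")
    if len(ratings):
        add("rating", task_col(ratings), "task")
    buttons = sel("button")
    if len(buttons):
        add("button", task_col(buttons, kind="delta"), "task")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_volumes:
            raise ValueError("motion series length must equal volume count")
        for j in range(motion.shape[1]):
            add(f"motion_{j}", motion[:, j], "nuisance")

    dct = highpass_basis(n_volumes, tr, highpass_cutoff)
    for k in range(dct.shape[1]):
        add(f"dct_{k + 1}", dct[:, k], "filter")
    add("intercept", np.ones(n_volumes), "intercept")

    return DesignMatrix(
        values=np.column_stack(columns),
        column_names=names,
        column_roles=roles,
        tr=tr,
        highpass_cutoff=highpass_cutoff,
        hrf=hrf,
    )
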