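"""Behavioral scoring for the free-recall task.

Turns the subjects x items recall indicator matrix into the two quantities
the imaging analyses consume: the per-subject recall count (the behavioral
outcome of every brain-behavior model) and per-item norm tables
(memorability = the across-subject mean recall of an item; arousal = the
across-subject mean arousal rating), which feed the parametric modulators.

Primacy and recency pictures are shown only to stabilize serial-position
effects; they carry an exclusion flag and never contribute to recall counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RecallMatrix",
    "score_recall",
    "compute_memorability",
    "compute_arousal_norms",
]


@dataclass
class RecallMatrix:
    """Binary subjects x items recall indicators plus item exclusion flags.

    Parameters
    ----------
    data : (n_subjects, n_items) array of {0, 1}
        ``data[s, i]`` is 1 iff subject ``s`` freely recalled item ``i``.
    excluded : (n_items,) bool array
        True for primacy/recency items, which are dropped from recall
        counts and from the memorability table.
    item_ids : (n_items,) int array, optional
        Stable item identifiers; defaults to ``0..n_items-1``.
    subject_ids : (n_subjects,) array, optional
        Defaults to ``0..n_subjects-1``.
    """

    data: np.ndarray
    excluded: np.ndarray
    item_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("recall data must be 2-D (subjects x items)")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("recall indicators must be 0/1")
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.excluded.shape != (self.data.shape[1],):
            raise ValueError("exclusion flags must have one entry per item")
        if self.item_ids is None:
            self.item_ids = np.arange(self.data.shape[1])
        if self.subject_ids is None:
            self.subject_ids = np.arange(self.data.shape[0])

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]


def score_recall(matrix: RecallMatrix) -> pd.DataFrame:
    """Per-subject count of recalled pictures, excluding primacy/recency items.

    Returns a phenotype-table fragment with columns ``subject_id`` and
    ``recall_count`` (integer row sums over non-excluded items).
    """
    included = ~matrix.excluded
    counts = matrix.data[:, included].sum(axis=1).astype(int)
    return pd.DataFrame(
        {"subject_id": matrix.subject_ids, "recall_count": counts}
    )


def compute_memorability(matrix: RecallMatrix) -> pd.DataFrame:
    """Item memorability: the average free-recall score of each picture.

    Column means over subjects, restricted to non-excluded items.  Requires
    at least one subject.
    """
    if matrix.n_subjects < 1:
        raise ValueError("memorability needs at least one subject")
    included = ~matrix.excluded
    means = matrix.data[:, included].mean(axis=0)
    return pd.DataFrame(
        {"item_id": matrix.item_ids[included], "memorability": means}
    )


def compute_arousal_norms(
    item_ids: np.ndarray, arousal_ratings: np.ndarray
) -> pd.DataFrame:
    """Per-item mean arousal table (join key ``item_id``).

    ``arousal_ratings`` may be a (n_subjects, n_items) matrix of per-subject
    ratings or a (n_items,) vector of pre-averaged norms.
    """
    arr = np.asarray(arousal_ratings, dtype=float)
    mean = arr.mean(axis=0) if arr.ndim == 2 else arr
    if mean.shape[0] != len(item_ids):
        raise ValueError("one arousal value required per item")
    return pd.DataFrame({"item_id": np.asarray(item_ids), "arousal": mean})
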