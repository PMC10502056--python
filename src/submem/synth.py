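"""Synthetic cohort generation.

Emulates a picture-encoding fMRI study with the statistical structure the
downstream analyses assume: an event schedule (0.5 s fixation + 2.5 s
picture + 9-12 s jittered intertrial period, 12-15 s per trial; target
pictures interleaved with scrambled geometrical figures so that target runs
are capped, valence runs capped at 4; primacy/recency pictures at the run
edges), a Rasch-like recall model P(recall) = logistic(ability_s +
easiness_i), and 4-D BOLD volumes composed of HRF-convolved condition
signals placed on ground-truth amplitude maps, spatially independent
network components with task-locked time courses, AR(1) temporal noise and
low-frequency drift.

All randomness flows from one master seed through named substreams
(``numpy.random.SeedSequence`` spawn keys): (0,) ground truth, (1, s)
subject s's events, (2, s) subject s's recall row, (3, s) subject s's BOLD
and motion, (4,) phenotype covariates.  Cohorts are therefore bit-identical
under the same spec and extensible in n_subjects without reshuffling
earlier subjects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .behavior import RecallMatrix, compute_memorability, score_recall
from .design import HRFSpec, build_task_regressor
from .glm import BoldRun

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "make_ground_truth",
    "generate_events",
    "generate_recall",
    "generate_bold",
    "generate_cohort",
]

logger = logging.getLogger("submem")

VALENCES = ("negative", "neutral", "positive")
MAX_VALENCE_RUN = 4
MAX_TARGET_RUN = 2  # design intent; relaxed when arithmetically infeasible


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for one synthetic cohort.

    Timing defaults reproduce the encoding task (2.5 s pictures after a
    0.5 s fixation cross, 9-12 s jittered intertrial period) and the item
    counts (72 target pictures, 24 scrambled geometrical figures, 2 primacy
    + 2 recency pictures).  Signal amplitudes are in units of the noise SD
    when ``noise_sigma = 1``.
    """

    n_subjects: int
    n_items: int = 72
    n_scrambled: int = 24
    n_primacy_recency: int = 4
    grid_shape: tuple[int, int, int] = (16, 16, 10)
    tr: float = 3.0
    picture_dur: float = 2.5
    fixation_dur: float = 0.5
    iti_range: tuple[float, float] = (9.0, 12.0)
    noise_sigma: float = 1.0
    ar_rho: float = 0.3
    drift_amp: float = 1.0
    seed: int = 0
    # signal amplitudes (fraction of noise SD at noise_sigma = 1)
    amp_encoding: float = 2.0
    amp_subsequent_memory: float = 1.5
    amp_individual_diff: float = 1.0
    amp_memorability: float = 0.5
    amp_network: float = 1.5
    # latent behavior scales
    ability_sd: float = 0.8
    easiness_sd: float = 1.0
    arousal_easiness_corr: float = 0.3
    # network arm
    n_networks: int = 4
    n_linked_networks: int = 2
    network_gain_corr: float = 0.7

    def __post_init__(self) -> None:
        if self.n_items < 0:
            raise ValueError("n_items must be non-negative")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not (0 <= self.ar_rho < 1):
            raise ValueError("ar_rho must lie in [0, 1)")
        if self.iti_range[0] > self.iti_range[1]:
            raise ValueError("iti_range must be ordered")
        if self.n_linked_networks > self.n_networks:
            raise ValueError("n_linked_networks cannot exceed n_networks")


@dataclass
class GroundTruth:
    """Latent quantities the analyses try to recover.

    ``item_easiness`` is the latent memorability scale (enters the recall
    model additively, higher = more often recalled); ``subject_ability`` the
    latent memory scale.  Amplitude maps: ``encoding_map`` (picture vs
    scrambled-figure activation), ``shared_effect_map`` (group-common
    subsequent-memory signal, also carries the memorability-proportional
    term), ``idiff_effect_map`` (per-subject amplitude proportional to
    ability).  ``network_maps`` are K_true spatial components whose
    task-locked time-course gains are ``network_timecourse_gains``; for
    behavior-linked components the gains correlate with ability.
    """

    item_easiness: np.ndarray
    subject_ability: np.ndarray
    encoding_map: np.ndarray
    shared_effect_map: np.ndarray
    idiff_effect_map: np.ndarray
    network_maps: np.ndarray  # (K_true, x, y, z)
    network_timecourse_gains: np.ndarray  # (n_subjects, K_true)
    linked_networks: np.ndarray  # indices of behavior-linked components
    item_arousal: np.ndarray
    edge_easiness: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _rng(spec: CohortSpec, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=spawn_key)
    )


def _gaussian_blob(
    grid: tuple[int, int, int], center: np.ndarray, sigma: float
) -> np.ndarray:
    axes = np.indices(grid).astype(float)
    d2 = sum((axes[i] - center[i]) ** 2 for i in range(3))
    blob = np.exp(-d2 / (2 * sigma**2))
    return blob / blob.max()


def make_ground_truth(spec: CohortSpec) -> GroundTruth:
    """Draw the latent cohort structure from the (0,) substream.

    Effect maps are Gaussian blobs at well-separated grid positions; network
    maps are checked to be pairwise near-orthogonal (|r| < 0.3) so that the
    spatial-independence assumption of the ICA arm holds by construction.
    """
    rng = _rng(spec, 0)
    grid = spec.grid_shape
    if min(grid) < 4:
        raise ValueError("grid too small to hold the requested effect maps")
    # item-level and spatial draws come first so that growing n_subjects
    # leaves them (and hence earlier subjects' events/recall) untouched
    easiness = rng.normal(0.0, spec.easiness_sd, spec.n_items)
    edge_easiness = rng.normal(1.5, 0.3, spec.n_primacy_recency)
    z = (easiness - easiness.mean()) / (easiness.std() or 1.0) if spec.n_items else easiness
    rho = spec.arousal_easiness_corr
    arousal = rho * z + math.sqrt(max(0.0, 1 - rho**2)) * rng.normal(
        0.0, 1.0, spec.n_items
    )

    gshape = np.array(grid, dtype=float)
    # fixed fractional anchor positions keep the three effect maps apart
    anchors = np.array([[0.25, 0.25, 0.4], [0.72, 0.3, 0.55], [0.3, 0.72, 0.6]])
    sigma = max(1.2, min(grid) / 6.0)
    encoding = _gaussian_blob(grid, anchors[0] * (gshape - 1), sigma)
    shared = _gaussian_blob(grid, anchors[1] * (gshape - 1), sigma)
    idiff = _gaussian_blob(grid, anchors[2] * (gshape - 1), sigma)

    k = spec.n_networks
    maps = np.zeros((k, *grid))
    flat = np.array(grid, dtype=float) - 1
    attempts = 0
    placed = 0
    while placed < k:
        attempts += 1
        if attempts > 500:
            raise ValueError("grid too small for the requested network count")
        center = rng.uniform(0.1, 0.9, 3) * flat
        cand = _gaussian_blob(grid, center, sigma * 0.8)
        ok = True
        for j in range(placed):
            r = np.corrcoef(cand.ravel(), maps[j].ravel())[0, 1]
            if abs(r) >= 0.3:
                ok = False
                break
        if ok:
            maps[placed] = cand
            placed += 1

    ability = rng.normal(0.0, spec.ability_sd, spec.n_subjects)
    linked = np.arange(spec.n_linked_networks)
    gains = rng.normal(0.0, 1.0, (spec.n_subjects, k))
    rho_g = spec.network_gain_corr
    if spec.n_subjects > 1 and ability.std() > 0:
        z_ab = (ability - ability.mean()) / ability.std()
        for j in linked:
            gains[:, j] = rho_g * z_ab + math.sqrt(1 - rho_g**2) * gains[:, j]
    gains = 1.0 + 0.5 * gains  # positive mean responsivity, subject spread

    return GroundTruth(
        item_easiness=easiness,
        subject_ability=ability,
        encoding_map=encoding,
        shared_effect_map=shared,
        idiff_effect_map=idiff,
        network_maps=maps,
        network_timecourse_gains=gains,
        linked_networks=linked,
        item_arousal=arousal,
        edge_easiness=edge_easiness,
    )


# -- event schedule ------------------------------------------------------------


def _target_run_cap(n_items: int, n_scrambled: int) -> int:
    """Longest allowed run of target pictures between scrambled separators.

    The design intent is a cap of 2, but with s separators at most
    2 * (s + 1) targets fit; when the item counts make 2 infeasible the cap
    is relaxed to ceil(n_items / (n_scrambled + 1)) and the discrepancy is
    logged.
    """
    if n_items == 0:
        return MAX_TARGET_RUN
    needed = math.ceil(n_items / (n_scrambled + 1))
    if needed > MAX_TARGET_RUN:
        logger.info(
            "target-run cap of %d infeasible for %d targets / %d separators; "
            "relaxed to %d",
            MAX_TARGET_RUN,
            n_items,
            n_scrambled,
            needed,
        )
        return needed
    return MAX_TARGET_RUN


def _interleave_sequence(
    n_items: int,
    n_scrambled: int,
    rng: np.random.Generator,
    cap: int | None = None,
) -> list[str]:
    """Random target/scrambled order with the target-run cap enforced."""
    if cap is None:
        cap = _target_run_cap(n_items, n_scrambled)
    slots = n_scrambled + 1
    if n_items > cap * slots:
        raise ValueError(
            "infeasible schedule: target-run cap "
            f"{cap} x {slots} gaps < {n_items} targets"
        )
    # distribute targets over the gaps between scrambled pictures, each <= cap
    counts = np.zeros(slots, dtype=int)
    remaining = n_items
    while remaining > 0:
        open_slots = np.flatnonzero(counts < cap)
        pick = rng.choice(open_slots)
        counts[pick] += 1
        remaining -= 1
    seq: list[str] = []
    for g in range(slots):
        seq.extend(["target"] * int(counts[g]))
        if g < n_scrambled:
            seq.append("scrambled")
    return seq


def _assign_valences(n_items: int, rng: np.random.Generator) -> list[str]:
    """Balanced valence labels with runs capped at 4 (greedy with retries)."""
    base = [VALENCES[i % 3] for i in range(n_items)]
    for _ in range(200):
        counts = {v: base.count(v) for v in VALENCES}
        out: list[str] = []
        run_val, run_len = None, 0
        dead = False
        for _pos in range(n_items):
            choices = [
                v
                for v in VALENCES
                if counts[v] > 0 and not (v == run_val and run_len >= MAX_VALENCE_RUN)
            ]
            if not choices:
                dead = True
                break
            probs = np.array([counts[v] for v in choices], dtype=float)
            v = rng.choice(choices, p=probs / probs.sum())
            out.append(v)
            counts[v] -= 1
            run_len = run_len + 1 if v == run_val else 1
            run_val = v
        if not dead:
            return out
    raise ValueError("infeasible schedule: valence-run cap of 4 not satisfiable")


def generate_events(spec: CohortSpec, subject_seed: int) -> pd.DataFrame:
    """One subject's event timeline as a BIDS-style table.

    Rows: picture events (trial_type primacy / target / scrambled / recency,
    2.5 s epochs), rating epochs (variable duration inside the intertrial
    period) and button presses (delta events at rating offset).  Each trial
    occupies fixation + picture + intertrial, so consecutive picture onsets
    differ by fixation_dur + picture_dur + iti with iti ~ U(iti_range).

    Columns: onset, duration, trial_type, item_id, valence.  Scrambled
    figures and rating/button rows carry item_id -1.
    """
    rng = np.random.default_rng(subject_seed)
    n_pre = spec.n_primacy_recency // 2
    n_post = spec.n_primacy_recency - n_pre

    order: list[tuple[str, int]] = []
    for j in range(n_pre):
        order.append(("primacy", spec.n_items + j))
    if spec.n_items or spec.n_scrambled:
        seq = _interleave_sequence(spec.n_items, spec.n_scrambled, rng)
        item_perm = rng.permutation(spec.n_items)
        it = iter(item_perm)
        for kind in seq:
            order.append((kind, int(next(it)) if kind == "target" else -1))
    for j in range(n_post):
        order.append(("recency", spec.n_items + n_pre + j))

    # map balanced, run-capped valences onto targets in presentation order
    valence = _assign_valences(spec.n_items, rng) if spec.n_items else []
    val_iter = iter(valence)
    val_by_item: dict[int, str] = {}
    for kind, item in order:
        if kind == "target":
            val_by_item[item] = next(val_iter)

    rows = []
    t = 0.0
    for kind, item in order:
        pic_on = t + spec.fixation_dur
        iti = rng.uniform(*spec.iti_range)
        rows.append(
            {
                "onset": pic_on,
                "duration": spec.picture_dur,
                "trial_type": kind,
                "item_id": item,
                "valence": val_by_item.get(item, "n/a"),
            }
        )
        rating_dur = rng.uniform(1.0, 4.0)
        rating_on = pic_on + spec.picture_dur
        rows.append(
            {
                "onset": rating_on,
                "duration": rating_dur,
                "trial_type": "rating",
                "item_id": -1,
                "valence": "n/a",
            }
        )
        rows.append(
            {
                "onset": rating_on + rating_dur,
                "duration": 0.0,
                "trial_type": "button",
                "item_id": -1,
                "valence": "n/a",
            }
        )
        t = pic_on + spec.picture_dur + iti
    df = pd.DataFrame(
        rows, columns=["onset", "duration", "trial_type", "item_id", "valence"]
    )
    df.attrs["run_length"] = t
    return df


# -- recall --------------------------------------------------------------------


def generate_recall(truth: GroundTruth, spec: CohortSpec) -> RecallMatrix:
    """Binary recall indicators under the logistic-additive model.

    ``P(recall_si) = logistic(ability_s + easiness_i)``; primacy/recency
    items (appended after the target items, with elevated easiness) are
    flagged excluded.  Each subject's row uses the (2, s) substream, so the
    matrix is row-extensible.
    """
    ease = np.concatenate([truth.item_easiness, truth.edge_easiness])
    n_sub = truth.subject_ability.shape[0]
    n_all = ease.shape[0]
    data = np.zeros((n_sub, n_all), dtype=np.int8)
    for s in range(n_sub):
        rng = _rng(spec, 2, s)
        logit = truth.subject_ability[s] + ease
        p = 1.0 / (1.0 + np.exp(-logit))
        data[s] = rng.random(n_all) < p
    excluded = np.zeros(n_all, dtype=bool)
    excluded[spec.n_items :] = True
    return RecallMatrix(data=data, excluded=excluded)


# -- BOLD ----------------------------------------------------------------------


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], rho: float, sigma: float
) -> np.ndarray:
    """Stationary AR(1) innovations along the last axis."""
    t = shape[-1]
    eps = rng.normal(0.0, 1.0, shape)
    out = np.empty(shape)
    scale = math.sqrt(1.0 - rho**2) if rho else 1.0
    out[..., 0] = eps[..., 0]
    for i in range(1, t):
        out[..., i] = rho * out[..., i - 1] + scale * eps[..., i]
    return sigma * out


def generate_bold(
    spec: CohortSpec,
    truth: GroundTruth,
    events: pd.DataFrame,
    recall_row: np.ndarray,
    subject_index: int,
    hrf: HRFSpec = HRFSpec(),
) -> BoldRun:
    """One subject's 4-D run.

    The volume equals baseline + HRF-convolved condition signals placed on
    the ground-truth maps (picture-vs-figure on the encoding map;
    later-recalled increment and a memorability-proportional term on the
    shared subsequent-memory map; an ability-scaled term on the
    individual-difference map) + network components times their task-locked
    time courses + AR(1) noise + low-frequency drift.  The volume count is
    ceil(run length / TR).  Six smooth random motion nuisance series are
    attached.
    """
    grid = spec.grid_shape
    if min(grid) < 4:
        raise ValueError("grid too small to hold the requested effect maps")
    run_length = float(events.attrs.get("run_length", 0.0)) or float(
        (events["onset"] + events["duration"]).max() + spec.iti_range[1]
    )
    n_vols = int(math.ceil(run_length / spec.tr))
    rng = _rng(spec, 3, subject_index)

    targets = events[events["trial_type"] == "target"]
    scram = events[events["trial_type"] == "scrambled"]

    def conv(sub: pd.DataFrame, amplitudes=None) -> np.ndarray:
        if len(sub) == 0:
            return np.zeros(n_vols)
        return build_task_regressor(
            sub["onset"].to_numpy(),
            sub["duration"].to_numpy(),
            n_vols,
            spec.tr,
            kind="epoch",
            hrf=hrf,
            amplitudes=amplitudes,
        )

    target_reg = conv(targets)
    scram_reg = conv(scram)

    item_idx = targets["item_id"].to_numpy(dtype=int)
    remembered = recall_row[item_idx].astype(float) if len(item_idx) else np.zeros(0)
    rem_reg = conv(targets, amplitudes=remembered)
    ease = truth.item_easiness[item_idx] if len(item_idx) else np.zeros(0)
    ease_centered = ease - ease.mean() if len(ease) else ease
    mem_reg = conv(targets, amplitudes=ease_centered)

    vol4 = np.zeros((*grid, n_vols))
    vol4 += 100.0  # baseline

    def place(map3: np.ndarray, series: np.ndarray) -> None:
        vol4[...] += map3[..., None] * series[None, None, None, :]

    ability = truth.subject_ability[subject_index]
    place(truth.encoding_map, spec.amp_encoding * target_reg)
    place(truth.shared_effect_map, spec.amp_subsequent_memory * rem_reg)
    place(truth.shared_effect_map, spec.amp_memorability * mem_reg)
    place(truth.idiff_effect_map, spec.amp_individual_diff * ability * target_reg)

    gains = truth.network_timecourse_gains[subject_index]
    for k in range(truth.network_maps.shape[0]):
        # evoked response plus component-specific spontaneous fluctuation
        # (the latter is what makes co-activated networks separable)
        tc = (
            spec.amp_network * gains[k] * target_reg
            + 0.3 * spec.amp_network * scram_reg
            + 0.7 * spec.amp_network * _ar1_noise(rng, (n_vols,), 0.5, 1.0)
        )
        place(truth.network_maps[k], tc)

    if spec.noise_sigma > 0:
        vol4 += _ar1_noise(rng, (*grid, n_vols), spec.ar_rho, spec.noise_sigma)
    if spec.drift_amp > 0:
        tt = np.arange(n_vols)
        slow = np.stack(
            [np.cos(np.pi * k * (2 * tt + 1) / (2 * n_vols)) for k in (1, 2, 3)]
        )
        coefs = rng.normal(0.0, spec.drift_amp, (*grid, 3))
        vol4 += np.einsum("xyzc,ct->xyzt", coefs, slow)

    motion = np.cumsum(rng.normal(0.0, 0.05, (n_vols, 6)), axis=0)
    motion -= motion.mean(axis=0)

    return BoldRun(
        data=vol4.astype(np.float32),
        tr=spec.tr,
        mask=np.ones(grid, dtype=bool),
        motion=motion,
        subject_id=subject_index,
    )


# -- full cohort ---------------------------------------------------------------


@dataclass
class Cohort:
    """Everything one synthetic study produces, plus its ground truth."""

    spec: CohortSpec
    truth: GroundTruth
    events: list[pd.DataFrame]
    recall: RecallMatrix
    runs: list[BoldRun]
    phenotype: pd.DataFrame
    memorability: pd.DataFrame


def _subject_seed(spec: CohortSpec, s: int) -> int:
    # deterministic per-subject integer seed below 2^31 (counter scheme)
    return int(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, s)).generate_state(1)[0]
        % (2**31)
    )


def generate_cohort(spec: CohortSpec, with_bold: bool = True) -> Cohort:
    """Generate ground truth, events, recall, phenotype and (optionally) BOLD.

    The events tables gain memorability (analyzed-cohort norm), arousal and
    remembered columns for target rows.  Phenotype covariates: age ~
    U(18, 35), sex in {F, M}, an MR batch factor with three levels and a
    recall-room factor with two levels, drawn from the (4,) substream.
    """
    truth = make_ground_truth(spec)
    recall = generate_recall(truth, spec)
    memo = compute_memorability(recall)
    memo_by_item = dict(zip(memo["item_id"], memo["memorability"]))
    arousal_by_item = dict(enumerate(truth.item_arousal))

    events_list: list[pd.DataFrame] = []
    runs: list[BoldRun] = []
    for s in range(spec.n_subjects):
        ev = generate_events(spec, _subject_seed(spec, s))
        is_target = ev["trial_type"] == "target"
        ev["memorability"] = np.where(
            is_target, ev["item_id"].map(memo_by_item), np.nan
        )
        ev["arousal"] = np.where(is_target, ev["item_id"].map(arousal_by_item), np.nan)
        rem = pd.Series(np.nan, index=ev.index)
        tgt_ids = ev.loc[is_target, "item_id"].to_numpy(dtype=int)
        rem[is_target] = recall.data[s, tgt_ids]
        ev["remembered"] = rem
        events_list.append(ev)
        if with_bold:
            runs.append(generate_bold(spec, truth, ev, recall.data[s], s))

    scores = score_recall(recall)
    prng = _rng(spec, 4)
    phenotype = pd.DataFrame(
        {
            "subject_id": scores["subject_id"],
            "recall_count": scores["recall_count"],
            "age": prng.uniform(18.0, 35.0, spec.n_subjects),
            "sex": prng.choice(["F", "M"], spec.n_subjects),
            "batch_mr": prng.choice(["mr1", "mr2", "mr3"], spec.n_subjects),
            "room": prng.choice(["room1", "room2"], spec.n_subjects),
        }
    )
    return Cohort(
        spec=spec,
        truth=truth,
        events=events_list,
        recall=recall,
        runs=runs,
        phenotype=phenotype,
        memorability=memo,
    )


def spec_to_dict(spec: CohortSpec) -> dict:
    """JSON-serializable view of a CohortSpec (for manifests/sidecars)."""
    d = asdict(spec)
    d["grid_shape"] = list(spec.grid_shape)
    d["iti_range"] = list(spec.iti_range)
    return d
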