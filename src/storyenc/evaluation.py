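"""Cross-validated two-alternative passage classification.

The trained encoding model is evaluated by a balanced decoding task: split
the run into contiguous cross-validation folds (90% train / 10% test by
default), cut each held-out block into non-overlapping 20-TR segments, and
for each segment ask the model to decide which of two candidate passages —
the true one and an alternative drawn at random from the other held-out
segments — produced the observed fMRI.  Each subject gets its own model; the
per-subject predicted segments are concatenated along the voxel axis into a
group time series (no cross-subject averaging), and the candidate whose
predicted group series is closer in Euclidean distance to the observed group
series wins.  Chance level is 50%; each true segment is paired with many
alternatives to reduce the variance of the accuracy estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SubjectData
from .design import DesignMatrix, build_lagged_design
from .encoding import VoxelEncoding, VoxelEncodingResults
from .stimulus import AnnotatedStory, FeatureTimeSeries, resample_to_tr, \
    select_feature_set

__all__ = [
    "FoldPlan", "SegmentSet", "ClassificationResult",
    "make_folds", "segment_series", "classify_pair", "group_concatenate",
    "run_classification", "classify_timeseries",
    "FoldPredictions", "fit_predict_folds", "score_predictions",
]


@dataclass
class FoldPlan:
    """Contiguous cross-validation blocks over the time axis.

    Held-out blocks partition ``[0, T)``; ``trim`` rows adjacent to each
    block boundary are dropped from training (they belong to neither side) so
    that hemodynamic carry-over from test stimuli cannot leak into training.
    """

    T: int
    n_folds: int
    trim: int
    blocks: list[tuple[int, int]]

    def held_rows(self, fold: int) -> np.ndarray:
        s, e = self.blocks[fold]
        return np.arange(s, e)

    def training_rows(self, fold: int) -> np.ndarray:
        s, e = self.blocks[fold]
        lo = max(0, s - self.trim)
        hi = min(self.T, e + self.trim)
        mask = np.ones(self.T, dtype=bool)
        mask[lo:hi] = False
        return np.flatnonzero(mask)


@dataclass
class SegmentSet:
    """Non-overlapping fixed-length segments inside the held-out blocks."""

    seg_len: int
    segments: list[tuple[int, int]]
    fold_of: list[int]

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def make_folds(T: int, n_folds: int = 10, trim: int = 4) -> FoldPlan:
    """Partition ``[0, T)`` into ``n_folds`` contiguous held-out blocks.

    Blocks hold about ``T / n_folds`` rows; the first ``T mod n_folds``
    blocks take the extra row.  ``trim`` rows on each side of a block are
    excluded from that fold's training rows.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2 (a single fold leaves no "
                         "training data)")
    if trim < 0:
        raise ValueError("trim must be non-negative")
    min_T = n_folds * (1 + 2 * trim)
    if T < min_T:
        raise ValueError(
            f"T={T} is too small for {n_folds} folds with trim {trim}; "
            f"need at least T={min_T}"
        )
    sizes = np.full(n_folds, T // n_folds)
    sizes[: T % n_folds] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    blocks = [(int(edges[i]), int(edges[i + 1])) for i in range(n_folds)]
    return FoldPlan(T=T, n_folds=n_folds, trim=trim, blocks=blocks)


def segment_series(plan: FoldPlan, seg_len: int = 20) -> SegmentSet:
    """Left-aligned maximal packing of ``seg_len`` segments per held block;
    leftover rows at the end of a block are unused."""
    if seg_len < 1:
        raise ValueError("seg_len must be >= 1")
    segments: list[tuple[int, int]] = []
    fold_of: list[int] = []
    for f, (s, e) in enumerate(plan.blocks):
        n = (e - s) // seg_len
        for k in range(n):
            segments.append((s + k * seg_len, s + (k + 1) * seg_len))
            fold_of.append(f)
    if not segments:
        raise ValueError(
            f"segment length {seg_len} exceeds every held-out block "
            f"(largest block: {max(e - s for s, e in plan.blocks)} TRs)"
        )
    return SegmentSet(seg_len=seg_len, segments=segments, fold_of=fold_of)


def classify_pair(observed: np.ndarray, predicted_true: np.ndarray,
                  predicted_alt: np.ndarray) -> float:
    """Nearest-prediction decision for one two-alternative trial.

    Returns 1 if the true passage's predicted group series is strictly closer
    (Euclidean) to the observation, 0 if the alternative is closer, and 0.5
    on an exact tie (unbiased under the null).
    """
    observed = np.asarray(observed, dtype=float)
    predicted_true = np.asarray(predicted_true, dtype=float)
    predicted_alt = np.asarray(predicted_alt, dtype=float)
    if observed.shape != predicted_true.shape or observed.shape != predicted_alt.shape:
        raise ValueError(
            f"shape mismatch: observed {observed.shape}, predicted_true "
            f"{predicted_true.shape}, predicted_alt {predicted_alt.shape}"
        )
    d_true = np.linalg.norm(observed - predicted_true)
    d_alt = np.linalg.norm(observed - predicted_alt)
    if d_true < d_alt:
        return 1.0
    if d_true > d_alt:
        return 0.0
    return 0.5


def group_concatenate(per_subject: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-subject segment matrices along the voxel axis.

    Subject order is the caller's list order; voxels are pooled, never
    averaged across subjects.
    """
    if not per_subject:
        raise ValueError("no subject matrices to concatenate")
    mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in per_subject]
    n_trs = {m.shape[0] for m in mats}
    if len(n_trs) > 1:
        raise ValueError(f"TR counts differ across subjects: {sorted(n_trs)}")
    return np.hstack(mats)


@dataclass
class ClassificationResult:
    """Outcome of the repeated two-alternative classification.

    ``n_correct`` counts ties as 0.5; ``per_segment`` holds one row per
    (fold, segment) with its mean score over pairings.
    """

    n_trials: int
    n_correct: float
    per_segment: pd.DataFrame
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials

    @property
    def margin(self) -> float:
        """Mean Euclidean distance margin ``d_alt - d_true`` per trial: a
        graded measure of decoding evidence that keeps discriminating where
        accuracy itself saturates at 1."""
        w = self.per_segment["n_pairings"]
        return float((self.per_segment["margin"] * w).sum() / w.sum())

    @property
    def per_fold(self) -> pd.Series:
        g = self.per_segment.groupby("fold")
        return g["score_sum"].sum() / g["n_pairings"].sum()

    def summary(self) -> str:
        lines = [
            "Two-alternative passage classification",
            "=" * 40,
            f"trials:    {self.n_trials}",
            f"correct:   {self.n_correct:g} (ties count 0.5)",
            f"accuracy:  {self.accuracy:.4f}  (chance = 0.5)",
            "",
            "per-fold accuracy:",
            self.per_fold.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


@dataclass
class FoldPredictions:
    """Standardized observed and predicted series per fold per subject.

    ``observed[f][s]`` and ``predicted[f][s]`` are full-length ``(T, V_s)``
    matrices on fold ``f``'s training standardization scale; only held-out
    rows of fold ``f`` are meaningful for scoring that fold.
    """

    plan: FoldPlan
    observed: list[list[np.ndarray]]
    predicted: list[list[np.ndarray]]
    penalties: list[list[np.ndarray]]


def fit_predict_folds(subjects: list[SubjectData], design: DesignMatrix,
                      plan: FoldPlan, penalty_grid=None, inner_folds: int = 5,
                      seed: int = 0) -> FoldPredictions:
    """Train one encoding model per (fold, subject) and predict all rows.

    Predictions and observations are returned on the standardized scale of
    each fold's training rows — the scale on which classification distances
    are computed.
    """
    observed, predicted, penalties = [], [], []
    for f in range(plan.n_folds):
        rows = plan.training_rows(f)
        obs_f, pred_f, pen_f = [], [], []
        for subj in subjects:
            model = VoxelEncoding(subj.fmri[rows], design.subset_rows(rows))
            res = model.fit(penalty_grid=penalty_grid,
                            inner_folds=inner_folds, seed=seed)
            pred_f.append(res.predict(design, scale="standardized"))
            obs_f.append(res.transform_endog(subj.fmri))
            pen_f.append(res.penalties)
        observed.append(obs_f)
        predicted.append(pred_f)
        penalties.append(pen_f)
    return FoldPredictions(plan=plan, observed=observed, predicted=predicted,
                           penalties=penalties)


def _pair_rng(seed: int, segment: int) -> np.random.Generator:
    # One stream per true segment, independent of which voxels are scored,
    # so whole-brain and searchlight runs with the same seed draw the same
    # alternative pairings.
    return np.random.default_rng(np.random.SeedSequence([seed, 7919, segment]))


def score_predictions(preds: FoldPredictions, segments: SegmentSet,
                      n_pairings: int = 10, seed: int = 0,
                      columns: list[np.ndarray] | None = None,
                      config: dict | None = None) -> ClassificationResult:
    """Score every held-out segment against sampled alternative passages.

    For a true segment in fold ``f``, both candidate predictions come from
    fold ``f``'s trained models: the model predicts the fMRI series for the
    true passage and for each alternative passage (any other held-out
    segment), and the nearest prediction to the observed group series wins.
    With ``n_pairings`` at least the number of available alternatives, all of
    them are used and the result is deterministic.  ``columns`` optionally
    restricts each subject to a voxel index subset (searchlight cubes).
    """
    if n_pairings < 1:
        raise ValueError("n_pairings must be >= 1")
    if segments.n_segments < 2:
        raise ValueError("need at least 2 segments to form an alternative")
    n_subjects = len(preds.observed[0])
    if columns is None:
        columns = [None] * n_subjects

    records = []
    total_trials = 0
    total_score = 0.0
    for j, (s, e) in enumerate(segments.segments):
        f = segments.fold_of[j]
        obs = group_concatenate([
            o[s:e] if c is None else o[s:e][:, c]
            for o, c in zip(preds.observed[f], columns)
        ])
        pred_true = group_concatenate([
            p[s:e] if c is None else p[s:e][:, c]
            for p, c in zip(preds.predicted[f], columns)
        ])
        alts = [k for k in range(segments.n_segments) if k != j]
        if n_pairings >= len(alts):
            chosen = alts
        else:
            rng = _pair_rng(seed, j)
            chosen = list(rng.choice(alts, size=n_pairings, replace=False))
        score_sum = 0.0
        margin_sum = 0.0
        d_true = np.linalg.norm(obs - pred_true)
        for k in chosen:
            sa, ea = segments.segments[k]
            pred_alt = group_concatenate([
                p[sa:ea] if c is None else p[sa:ea][:, c]
                for p, c in zip(preds.predicted[f], columns)
            ])
            d_alt = np.linalg.norm(obs - pred_alt)
            score_sum += 1.0 if d_true < d_alt else (0.0 if d_true > d_alt
                                                     else 0.5)
            margin_sum += d_alt - d_true
        records.append({"fold": f, "segment": j, "start": s, "end": e,
                        "n_pairings": len(chosen), "score_sum": score_sum,
                        "accuracy": score_sum / len(chosen),
                        "margin": margin_sum / len(chosen)})
        total_trials += len(chosen)
        total_score += score_sum
    return ClassificationResult(
        n_trials=total_trials, n_correct=total_score,
        per_segment=pd.DataFrame(records), seed=seed,
        config=dict(config or {}),
    )


def classify_timeseries(subjects: list[SubjectData], fts: FeatureTimeSeries,
                        *, n_lags: int = 4, n_folds: int = 10,
                        trim: int | None = None, seg_len: int = 20,
                        n_pairings: int = 10, penalty_grid=None,
                        inner_folds: int = 5, seed: int = 0) -> ClassificationResult:
    """Run the full cross-validated classification from a TR-aligned series."""
    T = fts.n_trs
    for subj in subjects:
        if subj.n_trs != T:
            raise ValueError(
                f"subject {subj.subject_id} has {subj.n_trs} TRs but the "
                f"feature series has {T}"
            )
    if trim is None:
        trim = n_lags
    design = build_lagged_design(fts, n_lags=n_lags)
    plan = make_folds(T, n_folds=n_folds, trim=trim)
    segments = segment_series(plan, seg_len=seg_len)
    preds = fit_predict_folds(subjects, design, plan,
                              penalty_grid=penalty_grid,
                              inner_folds=inner_folds, seed=seed)
    cfg = {"n_lags": n_lags, "n_folds": n_folds, "trim": trim,
           "seg_len": seg_len, "n_pairings": n_pairings,
           "inner_folds": inner_folds}
    return score_predictions(preds, segments, n_pairings=n_pairings,
                             seed=seed, config=cfg)


def run_classification(subjects: list[SubjectData], story: AnnotatedStory,
                       *, feature_set: str | None = None, tr: float = 2.0,
                       n_lags: int = 4, n_folds: int = 10,
                       trim: int | None = None, seg_len: int = 20,
                       n_pairings: int = 10, penalty_grid=None,
                       inner_folds: int = 5, seed: int = 0) -> ClassificationResult:
    """Whole-pipeline entry point: story annotations in, accuracy out.

    With ``feature_set`` given, only that named group of story features
    annotates the passages (the single-feature-set variant used to build
    representation maps); with ``None`` all features are used.
    """
    fts = resample_to_tr(story, tr)
    if feature_set is not None:
        fts = select_feature_set(fts, feature_set, story)
    return classify_timeseries(
        subjects, fts, n_lags=n_lags, n_folds=n_folds, trim=trim,
        seg_len=seg_len, n_pairings=n_pairings, penalty_grid=penalty_grid,
        inner_folds=inner_folds, seed=seed,
    )
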