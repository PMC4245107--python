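"""Word-level story annotations and their TR-aligned feature time series.

A story presented by rapid serial visual presentation (RSVP, one word every
0.5 s) is described by a feature vector per word: indicator columns for
discrete annotations (part of speech, character mentions, dialog, ...) and
real-valued columns for continuous ones (word length, embedding dimensions).
Because fMRI volumes arrive once per TR (2 s), the per-word vectors are
collapsed by summing all words whose onsets fall inside each TR interval,
yielding the feature magnitude series ``x_f(t)`` that the encoding model
consumes.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AnnotatedStory",
    "FeatureTimeSeries",
    "resample_to_tr",
    "select_feature_set",
    "annotate_word_length",
    "read_annotations",
    "read_feature_sets",
    "write_annotations",
]

#: Duration each word stays on screen under RSVP, seconds.
DEFAULT_WORD_DURATION = 0.5


@dataclass
class AnnotatedStory:
    """Per-word stimulus description: tokens, onsets and feature values.

    Parameters
    ----------
    words
        Presented tokens, one per row of ``features``.
    onsets
        Word onset times in seconds from run start, strictly increasing.
    features
        ``(n_words, n_features)`` array of real feature values.
    feature_names
        Unique column names for ``features``.
    feature_sets
        Named groups of columns, e.g. ``{"visual": ["word_length"], ...}``.
        Every member must name an existing column.
    word_duration
        Seconds each word is displayed (0.5 under RSVP).
    run_length
        Declared run length in seconds.  Defaults to ``last onset +
        word_duration``; trailing empty TRs become zero rows on resampling.
    """

    words: list[str]
    onsets: np.ndarray
    features: np.ndarray
    feature_names: list[str]
    feature_sets: dict[str, list[str]] = field(default_factory=dict)
    word_duration: float = DEFAULT_WORD_DURATION
    run_length: float | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if len(self.words) != len(self.onsets):
            raise ValueError("words and onsets must have equal length")
        if self.features.shape[0] != len(self.words):
            raise ValueError("features must have one row per word")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match feature columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if np.any(np.isnan(self.features)):
            raise ValueError("features contain NaN")
        if len(self.onsets) and np.any(self.onsets < 0):
            raise ValueError("onsets must be non-negative")
        if len(self.onsets) > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        for set_name, members in self.feature_sets.items():
            unknown = [m for m in members if m not in self.feature_names]
            if unknown:
                raise ValueError(
                    f"feature set {set_name!r} names unknown columns: {unknown}"
                )
        if self.run_length is not None:
            end = self.duration_from_words()
            if self.run_length < end:
                # name the first offending word for the caller
                bad = int(np.argmax(self.onsets + self.word_duration > self.run_length))
                raise ValueError(
                    f"word {bad} ({self.words[bad]!r}) at onset "
                    f"{self.onsets[bad]:g} s extends beyond the declared run "
                    f"length of {self.run_length:g} s"
                )

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def duration_from_words(self) -> float:
        """End of the last word's presentation, seconds."""
        if len(self.onsets) == 0:
            return 0.0
        return float(self.onsets[-1] + self.word_duration)

    @property
    def duration(self) -> float:
        """Effective run length used for resampling."""
        return self.run_length if self.run_length is not None else self.duration_from_words()


@dataclass
class FeatureTimeSeries:
    """TR-aligned feature magnitudes ``x_f(t)``: one row per TR."""

    values: np.ndarray
    tr: float
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match value columns")
        if np.any(np.isnan(self.values)):
            raise ValueError("values contain NaN")

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def resample_to_tr(story: AnnotatedStory, tr: float) -> FeatureTimeSeries:
    """Collapse per-word feature vectors into per-TR sums.

    Row ``t`` of the output is the sum of the feature vectors of all words
    with onset in the half-open interval ``[t*tr, (t+1)*tr)``; a word exactly
    on a TR boundary belongs to the later bin.  Column sums are conserved.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    n_trs = max(1, math.ceil(story.duration / tr - 1e-12))
    out = np.zeros((n_trs, story.n_features))
    if story.n_words:
        bins = np.floor(story.onsets / tr + 1e-12).astype(int)
        beyond = bins >= n_trs
        if np.any(beyond):
            bad = int(np.argmax(beyond))
            raise ValueError(
                f"word {bad} ({story.words[bad]!r}) at onset {story.onsets[bad]:g} s "
                f"lies beyond the run length of {story.duration:g} s"
            )
        np.add.at(out, bins, story.features)
    return FeatureTimeSeries(out, tr=tr, feature_names=list(story.feature_names))


def select_feature_set(
    fts: FeatureTimeSeries, set_name: str, story: AnnotatedStory
) -> FeatureTimeSeries:
    """Restrict a feature time series to one named feature set.

    Columns come out in the order declared in ``story.feature_sets``;
    values are untouched.
    """
    if set_name not in story.feature_sets:
        available = sorted(story.feature_sets)
        raise KeyError(
            f"unknown feature set {set_name!r}; available sets: {available}"
        )
    members = list(story.feature_sets[set_name])
    missing = [m for m in members if m not in fts.feature_names]
    if missing:
        raise KeyError(f"feature set {set_name!r} names columns absent from the "
                       f"time series: {missing}")
    cols = [fts.feature_names.index(m) for m in members]
    return FeatureTimeSeries(fts.values[:, cols], tr=fts.tr, feature_names=members)


def annotate_word_length(words: list[str]) -> np.ndarray:
    """Number of letters per word: alphabetic characters only.

    Hyphens, apostrophes and digits are not letters, so "broom-stick"
    counts 10.
    """
    if not words:
        raise ValueError("empty token list")
    if any(not isinstance(w, str) or w == "" for w in words):
        raise ValueError("tokens must be non-empty strings")
    return np.array([sum(c.isalpha() for c in w) for w in words], dtype=float)


# ---------------------------------------------------------------------------
# File formats: word annotation TSV and feature-set grouping YAML.

def read_annotations(
    path, feature_sets: dict[str, list[str]] | None = None,
    word_duration: float = DEFAULT_WORD_DURATION,
) -> AnnotatedStory:
    """Read a word annotation TSV: ``token  onset  <feature_1> ...``.

    Comment lines starting with ``#`` may declare metadata, in particular
    ``# run_length: <seconds>``.
    """
    run_length = None
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.lower().startswith("run_length"):
                run_length = float(stripped.split(":", 1)[1])
        else:
            body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    if list(df.columns[:2]) != ["token", "onset"]:
        raise ValueError("annotation TSV must start with columns 'token' and 'onset'")
    feature_names = list(df.columns[2:])
    return AnnotatedStory(
        words=[str(w) for w in df["token"]],
        onsets=df["onset"].to_numpy(dtype=float),
        features=df[feature_names].to_numpy(dtype=float),
        feature_names=feature_names,
        feature_sets=feature_sets or {},
        word_duration=word_duration,
        run_length=run_length,
    )


def write_annotations(story: AnnotatedStory, path) -> None:
    """Write the annotation TSV (inverse of :func:`read_annotations`)."""
    df = pd.DataFrame(story.features, columns=story.feature_names)
    df.insert(0, "onset", story.onsets)
    df.insert(0, "token", story.words)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# run_length: {story.duration:g}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_feature_sets(path) -> dict[str, list[str]]:
    """Read the YAML grouping file mapping set name -> list of columns."""
    with open(path, "r", encoding="utf-8") as fh:
        sets = yaml.safe_load(fh)
    if not isinstance(sets, dict):
        raise ValueError("feature-set file must map set names to column lists")
    return {str(k): [str(c) for c in v] for k, v in sets.items()}
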