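"""Empirical chance distributions, permutation p-values and BH-FDR control.

Accuracy maps are assessed against an empirical distribution of chance-level
performance: each permutation circularly shifts the story feature series by
a random offset before training, which destroys the stimulus-response
alignment while preserving the temporal autocorrelation of both series
(segment-label shuffling would not).  Per-location p-values use the add-one
permutation estimator and maps are corrected for multiple comparisons with
the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data import SubjectData
from .evaluation import classify_timeseries
from .stimulus import AnnotatedStory, FeatureTimeSeries, resample_to_tr, \
    select_feature_set

__all__ = ["NullDistribution", "empirical_null", "pvalue", "fdr_bh",
           "top_k_mask"]


@dataclass
class NullDistribution:
    """Pooled chance-level accuracies from permuted runs."""

    accuracies: np.ndarray
    scheme: str = "circular feature shift"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float).ravel()
        if self.accuracies.size < 1:
            raise ValueError("null distribution is empty")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("null accuracies must lie in [0, 1]")

    @property
    def n_permutations(self) -> int:
        return self.accuracies.size

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())


def empirical_null(subjects: list[SubjectData], story: AnnotatedStory,
                   *, feature_set: str | None = None, n_permutations: int = 20,
                   tr: float = 2.0, seg_len: int = 20, seed: int = 0,
                   **classify_kwargs) -> NullDistribution:
    """Estimate the chance-level accuracy distribution by circular shifts.

    Each permutation rotates the TR-aligned feature series by a uniform
    random offset of at least ``2 * seg_len`` TRs (and at most
    ``T - 2 * seg_len``), retrains the models and reruns the classification.
    Requires ``T >= 4 * seg_len`` so that a valid offset exists.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    fts = resample_to_tr(story, tr)
    if feature_set is not None:
        fts = select_feature_set(fts, feature_set, story)
    T = fts.n_trs
    if T < 4 * seg_len:
        raise ValueError(
            f"T={T} leaves no admissible circular shift for segment length "
            f"{seg_len}; need T >= {4 * seg_len}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    accs = np.empty(n_permutations)
    for b in range(n_permutations):
        shift = int(rng.integers(2 * seg_len, T - 2 * seg_len + 1))
        shifted = FeatureTimeSeries(np.roll(fts.values, shift, axis=0),
                                    tr=fts.tr,
                                    feature_names=list(fts.feature_names))
        res = classify_timeseries(subjects, shifted, seg_len=seg_len,
                                  seed=seed, **classify_kwargs)
        accs[b] = res.accuracy
    return NullDistribution(accs, seed=seed)


def pvalue(accuracy: float, null: NullDistribution) -> float:
    """Add-one permutation p-value: ``(1 + #{null >= acc}) / (1 + n)``.

    Never exactly zero; ties with null values count against the observation.
    """
    n_ge = int(np.sum(null.accuracies >= accuracy))
    return (1 + n_ge) / (1 + null.n_permutations)


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: reject the k smallest p-values where k is
    the largest i with ``p_(i) <= i * q / m``.

    Returns ``(reject mask, monotone BH-adjusted q-values)``.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals


def top_k_mask(values, k: int = 1000) -> np.ndarray:
    """Boolean mask of the ``k`` largest finite values.

    The threshold-free alternative to FDR maps: colour the top-K voxels (or
    centres) per feature set instead of the significant ones.
    """
    v = np.asarray(values, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = np.zeros(v.size, dtype=bool)
    finite = np.flatnonzero(np.isfinite(v))
    if finite.size == 0:
        return mask
    order = finite[np.argsort(v[finite])[::-1]]
    mask[order[:min(k, finite.size)]] = True
    return mask
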