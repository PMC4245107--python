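"""Lagged design matrices and train-fold standardization.

The hemodynamic response to a word persists for roughly 8 s, so a voxel's
activity at TR ``t`` is modelled as a linear combination of every feature's
magnitude at the preceding lags ``t-1 .. t-L`` (2-8 s before, at a 2 s TR,
for the default L = 4).  The lagged design matrix materialises those shifted
copies; the per-feature weights over lags are the finite-impulse-response
"response signatures" the encoding model estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import FeatureTimeSeries

__all__ = ["DesignMatrix", "build_lagged_design", "Standardizer", "standardize"]


@dataclass
class DesignMatrix:
    """``(T, F*L)`` matrix of lag-shifted feature magnitudes.

    Columns are ordered feature-major, lag-minor: column ``(f, d)`` sits at
    ``f*L + (d-1)`` and holds ``x_f(t-d)`` with zero padding for ``t-d < 0``,
    so reshaping a weight row to ``(F, L)`` yields per-feature signatures.
    """

    values: np.ndarray
    n_lags: int
    tr: float
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        expected = len(self.feature_names) * self.n_lags
        if self.values.shape[1] != expected:
            raise ValueError(
                f"design has {self.values.shape[1]} columns, expected F*L = {expected}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def lag_seconds(self) -> list[float]:
        """Time offsets of the lags: ``[tr, 2*tr, ..., L*tr]`` seconds."""
        return [self.tr * d for d in range(1, self.n_lags + 1)]

    @property
    def column_index(self) -> dict[tuple[str, int], int]:
        """Map ``(feature name, lag d)`` -> column position."""
        return {
            (name, d): f * self.n_lags + (d - 1)
            for f, name in enumerate(self.feature_names)
            for d in range(1, self.n_lags + 1)
        }

    def column_of(self, feature: str, lag: int) -> int:
        if feature not in self.feature_names:
            raise KeyError(f"unknown feature {feature!r}")
        if not 1 <= lag <= self.n_lags:
            raise KeyError(f"lag {lag} outside 1..{self.n_lags}")
        return self.feature_names.index(feature) * self.n_lags + (lag - 1)

    def subset_rows(self, rows: np.ndarray) -> "DesignMatrix":
        """Row-subset container (training-fold views); lag structure metadata
        is retained for column bookkeeping."""
        return DesignMatrix(self.values[rows], self.n_lags, self.tr,
                            list(self.feature_names))


def build_lagged_design(fts: FeatureTimeSeries, n_lags: int = 4) -> DesignMatrix:
    """Stack lag-shifted copies of each feature column.

    ``X[t, col(f, d)] = x_f(t - d)`` for ``d = 1..n_lags``, zero when
    ``t - d < 0``: a feature exerts influence only after its onset, over the
    following ``n_lags * tr`` seconds.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    T = fts.n_trs
    if n_lags >= T:
        raise ValueError(f"n_lags ({n_lags}) must be smaller than the series "
                         f"length ({T})")
    F = fts.n_features
    X = np.zeros((T, F * n_lags))
    for f in range(F):
        for d in range(1, n_lags + 1):
            X[d:, f * n_lags + (d - 1)] = fts.values[:-d, f]
    return DesignMatrix(X, n_lags=n_lags, tr=fts.tr,
                        feature_names=list(fts.feature_names))


class Standardizer:
    """Column-wise z-scoring with statistics from a training row subset.

    Means and scales are estimated on ``stats_from`` rows only and re-applied
    verbatim to held-out rows, so no test-set information leaks into training.
    Constant columns map to zero with recorded scale 1.
    """

    def __init__(self) -> None:
        self.means_: np.ndarray | None = None
        self.scales_: np.ndarray | None = None

    def fit(self, A: np.ndarray, stats_from: np.ndarray | None = None) -> "Standardizer":
        A = np.atleast_2d(np.asarray(A, dtype=float))
        rows = A if stats_from is None else A[stats_from]
        if rows.shape[0] == 0:
            raise ValueError("stats_from selects no rows")
        self.means_ = rows.mean(axis=0)
        scales = rows.std(axis=0)
        scales[scales == 0] = 1.0
        self.scales_ = scales
        return self

    def _check(self) -> None:
        if self.means_ is None:
            raise RuntimeError("Standardizer is not fitted")

    def transform(self, A: np.ndarray) -> np.ndarray:
        self._check()
        return (np.asarray(A, dtype=float) - self.means_) / self.scales_

    def fit_transform(self, A, stats_from=None) -> np.ndarray:
        return self.fit(A, stats_from).transform(A)

    def inverse_transform(self, A: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(A, dtype=float) * self.scales_ + self.means_


def standardize(
    X: DesignMatrix, Y: np.ndarray, stats_from: np.ndarray | None = None
) -> tuple[DesignMatrix, np.ndarray, Standardizer, Standardizer]:
    """Z-score design columns and voxel columns with training-row statistics.

    Returns the transformed design, the transformed fMRI matrix, and the two
    fitted :class:`Standardizer` records (design, fmri) needed to apply the
    identical transform to held-out rows or to undo it.
    """
    sx = Standardizer().fit(X.values, stats_from)
    sy = Standardizer().fit(Y, stats_from)
    Xs = DesignMatrix(sx.transform(X.values), X.n_lags, X.tr, list(X.feature_names))
    return Xs, sy.transform(Y), sx, sy
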