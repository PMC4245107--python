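"""Per-voxel ridge encoding model with cross-validated per-voxel penalties.

Each voxel's activity is modelled independently as a linear combination of
all lagged feature magnitudes; the ``L`` weights of one feature at one voxel
form that voxel's temporal response signature for the feature, estimated with
no assumed hemodynamic shape.  Ridge (L2) regularization handles the large
covariate count (F features x L lags), and the penalty is selected per voxel
by inner cross-validation: noisy voxels end up with very large penalties
(weights shrunk toward zero), effectively an automatic voxel selection.

The model/results split follows the statsmodels convention:

>>> model = VoxelEncoding(Y_train, design_train)      # doctest: +SKIP
>>> res = model.fit(penalty_grid=np.logspace(0, 7, 8))
>>> res.predict(design_full, scale="standardized")
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignMatrix, Standardizer

__all__ = ["VoxelEncoding", "VoxelEncodingResults", "fit_ridge",
           "DEFAULT_PENALTY_GRID"]

#: Logarithmic penalty grid, 10^0 .. 10^7 in decade steps.
DEFAULT_PENALTY_GRID = np.logspace(0, 7, 8)


def _ridge_solve_eigh(X: np.ndarray, Y: np.ndarray,
                      lambdas: np.ndarray) -> np.ndarray:
    """Exact penalized least-squares weights for per-voxel penalties.

    Solves ``(X'X + lambda_v I) w_v = X' y_v`` for every voxel via one shared
    eigendecomposition of ``X'X``; cost is one ``P x P`` eigh plus matrix
    products, independent of the number of distinct penalties.

    Returns ``(V, P)`` weights.
    """
    evals, evecs = np.linalg.eigh(X.T @ X)
    B = evecs.T @ (X.T @ Y)                       # (P, V) in the eigenbasis
    scaled = B / (evals[:, None] + lambdas[None, :])
    return (evecs @ scaled).T


def _contiguous_blocks(n: int, k: int) -> list[np.ndarray]:
    """Split range(n) into k contiguous blocks, remainders to the first."""
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(edges[i], edges[i + 1]) for i in range(k)]


class VoxelEncoding:
    """Linear encoding model of fMRI activity from a lagged story design.

    Parameters
    ----------
    endog
        ``(T, V)`` training fMRI matrix (one column per voxel).
    design
        :class:`~storyenc.design.DesignMatrix` over the same ``T`` rows.
    standardize
        Z-score design and voxel columns on the training rows before fitting
        (default).  With ``False`` the model is fitted on the raw scale and
        the recorded transform is the identity.
    """

    def __init__(self, endog: np.ndarray, design: DesignMatrix,
                 standardize: bool = True) -> None:
        endog = np.atleast_2d(np.asarray(endog, dtype=float))
        if endog.ndim == 2 and endog.shape[0] == 1 and design.values.shape[0] > 1:
            endog = endog.T
        if endog.shape[0] != design.values.shape[0]:
            raise ValueError(
                f"endog has {endog.shape[0]} rows but the design has "
                f"{design.values.shape[0]}"
            )
        if np.any(np.isnan(endog)) or np.any(np.isnan(design.values)):
            raise ValueError("NaN in model inputs")
        self.endog = endog
        self.design = design
        self.standardize = standardize

    @property
    def nobs(self) -> int:
        return self.endog.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.endog.shape[1]

    def fit(self, penalty_grid=None, inner_folds: int = 5,
            seed: int = 0, tie_tol: float = 5e-3) -> "VoxelEncodingResults":
        """Select a penalty per voxel by inner cross-validation and refit.

        The training rows are split into ``inner_folds`` contiguous blocks
        (contiguous, to respect fMRI temporal autocorrelation); for each
        candidate penalty the mean held-out squared error is accumulated, the
        per-voxel minimiser chosen, and final weights solve the penalized
        normal equations on all training rows.  Ties — any penalty whose CV
        error is within a relative ``tie_tol`` of the minimum — are broken
        toward the largest such penalty (more shrinkage), so pure-noise
        voxels whose error curve is flat at the top of the grid land on very
        high penalties, an automatic voxel down-weighting.  Deterministic
        given ``seed`` (the contiguous split scheme itself uses no
        randomness).
        """
        grid = np.asarray(
            DEFAULT_PENALTY_GRID if penalty_grid is None else penalty_grid,
            dtype=float,
        ).ravel()
        if grid.size == 0:
            raise ValueError("penalty_grid is empty")
        if np.any(grid < 0):
            raise ValueError("penalties must be non-negative")
        grid = np.sort(grid)
        if inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if grid.size > 1 and self.nobs < inner_folds:
            raise ValueError(
                f"{self.nobs} rows cannot be split into {inner_folds} inner folds"
            )

        sx = Standardizer().fit(self.design.values if self.standardize
                                else np.zeros((1, self.design.values.shape[1])))
        sy = Standardizer().fit(self.endog if self.standardize
                                else np.zeros((1, self.endog.shape[1])))
        if not self.standardize:
            sx.means_[:] = 0.0
            sx.scales_[:] = 1.0
            sy.means_[:] = 0.0
            sy.scales_[:] = 1.0
        Xs = sx.transform(self.design.values)
        Ys = sy.transform(self.endog)
        V = self.n_voxels

        if grid.size == 1:
            penalties = np.full(V, grid[0])
            cv_mse = None
        else:
            mse = np.zeros((grid.size, V))
            for val_rows in _contiguous_blocks(self.nobs, inner_folds):
                train_mask = np.ones(self.nobs, dtype=bool)
                train_mask[val_rows] = False
                Xtr, Ytr = Xs[train_mask], Ys[train_mask]
                Xva, Yva = Xs[val_rows], Ys[val_rows]
                evals, evecs = np.linalg.eigh(Xtr.T @ Xtr)
                B = evecs.T @ (Xtr.T @ Ytr)
                XvaQ = Xva @ evecs
                for i, lam in enumerate(grid):
                    resid = XvaQ @ (B / (evals[:, None] + lam)) - Yva
                    mse[i] += np.mean(resid**2, axis=0)
            # largest penalty whose CV error near-ties the minimum
            thresh = mse.min(axis=0) * (1.0 + tie_tol)
            ok = mse <= thresh[None, :]
            choice = (grid.size - 1) - np.argmax(ok[::-1], axis=0)
            penalties = grid[choice]
            cv_mse = mse / inner_folds

        weights = _ridge_solve_eigh(Xs, Ys, penalties)
        return VoxelEncodingResults(
            model=self, weights=weights, penalties=penalties,
            penalty_grid=grid, cv_mse=cv_mse, x_scaler=sx, y_scaler=sy,
        )


@dataclass
class VoxelEncodingResults:
    """Fitted per-voxel ridge weights, penalties and the standardization record.

    ``weights`` is ``(V, F*L)`` on the standardized scale; ``penalties`` holds
    the selected ``lambda_v`` per voxel.
    """

    model: VoxelEncoding
    weights: np.ndarray
    penalties: np.ndarray
    penalty_grid: np.ndarray
    cv_mse: np.ndarray | None
    x_scaler: Standardizer
    y_scaler: Standardizer

    @property
    def design(self) -> DesignMatrix:
        return self.model.design

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    @property
    def weights_original(self) -> np.ndarray:
        """Weights mapped back to the raw data scale.

        A standardized-scale weight relates z-scored design to z-scored
        activity; multiplying by ``sd(y_v) / sd(x_col)`` recovers the slope in
        original units (intercepts live in the recorded means).
        """
        return self.weights * (self.y_scaler.scales_[:, None]
                               / self.x_scaler.scales_[None, :])

    def signatures(self, scale: str = "original") -> np.ndarray:
        """Response signatures reshaped to ``(V, F, L)``."""
        W = self.weights_original if scale == "original" else self.weights
        V = self.n_voxels
        return W.reshape(V, self.design.n_features, self.design.n_lags)

    def extract_signature(self, voxel: int, feature: str,
                          scale: str = "original") -> np.ndarray:
        """The L-point response curve of one voxel to one feature,
        ordered by lag (first point = earliest lag)."""
        if feature not in self.design.feature_names:
            raise KeyError(
                f"unknown feature {feature!r}; known: {self.design.feature_names}"
            )
        f = self.design.feature_names.index(feature)
        return self.signatures(scale=scale)[voxel, f, :]

    def transform_endog(self, Y: np.ndarray) -> np.ndarray:
        """Apply the recorded voxel standardization to new fMRI rows."""
        return self.y_scaler.transform(Y)

    def predict(self, design: DesignMatrix | None = None,
                scale: str = "original") -> np.ndarray:
        """Predicted fMRI time series for a (possibly held-out) design.

        The design is standardized with the recorded training statistics,
        multiplied by the weights, and — for ``scale="original"`` —
        inverse-transformed to raw units (a zero standardized design thus
        predicts each voxel's recorded training mean).
        """
        if design is None:
            design = self.design
        if design.feature_names != self.design.feature_names or \
                design.n_lags != self.design.n_lags:
            mine = set(self.design.column_index)
            theirs = set(design.column_index)
            raise ValueError(
                "design columns do not match the fitted model; offending "
                f"columns: {sorted(mine ^ theirs)[:6]}"
            )
        Xs = self.x_scaler.transform(design.values)
        Yhat = Xs @ self.weights.T
        if scale == "original":
            Yhat = self.y_scaler.inverse_transform(Yhat)
        elif scale != "standardized":
            raise ValueError("scale must be 'original' or 'standardized'")
        return Yhat

    def score(self, Y: np.ndarray, design: DesignMatrix | None = None) -> np.ndarray:
        """Per-voxel Pearson correlation between prediction and observation."""
        Yhat = self.predict(design, scale="original")
        Yc = Y - Y.mean(axis=0)
        Pc = Yhat - Yhat.mean(axis=0)
        num = (Yc * Pc).sum(axis=0)
        den = np.sqrt((Yc**2).sum(axis=0) * (Pc**2).sum(axis=0))
        out = np.full(Y.shape[1], np.nan)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        return out

    def summary(self) -> str:
        """Plain-text overview of the fit."""
        import pandas as pd

        lam, counts = np.unique(self.penalties, return_counts=True)
        tbl = pd.DataFrame({"penalty": lam, "n_voxels": counts})
        lines = [
            "Voxelwise ridge encoding model",
            "=" * 38,
            f"observations (TRs):  {self.model.nobs}",
            f"voxels:              {self.n_voxels}",
            f"features x lags:     {self.design.n_features} x {self.design.n_lags}"
            f" = {self.weights.shape[1]} covariates",
            f"lag offsets (s):     {self.design.lag_seconds}",
            "",
            "selected penalties:",
            tbl.to_string(index=False),
        ]
        return "\n".join(lines)


def fit_ridge(X: DesignMatrix, Y: np.ndarray, penalty_grid=None,
              inner_folds: int = 5, seed: int = 0,
              standardize: bool = True) -> VoxelEncodingResults:
    """Functional wrapper: ``VoxelEncoding(Y, X, standardize).fit(...)``."""
    return VoxelEncoding(Y, X, standardize=standardize).fit(
        penalty_grid=penalty_grid, inner_folds=inner_folds, seed=seed
    )
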