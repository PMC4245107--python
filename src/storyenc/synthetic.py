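"""Synthetic stories and multi-subject fMRI generated from the model's own
generative equation, so every pipeline stage is testable without any
download.

A story is a sequence of RSVP words (one per 0.5 s) carrying a mix of sparse
0/1 indicator features (part-of-speech-like, character-mention-like) and
positive right-skewed continuous features (word-length-like, embedding-like),
partitioned into the canonical named sets (visual, syntax, semantics,
discourse).  Brain data follows the encoding equation exactly: voxels inside
a "driven" region respond to one feature set through a double-gamma-shaped
4-point response signature with random per-voxel amplitudes; everything else
is AR(1) noise, and per-subject anatomical variability is emulated by a
whole-grid millimetre translation.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .data import SubjectData
from .design import build_lagged_design
from .stimulus import AnnotatedStory, annotate_word_length, resample_to_tr

__all__ = [
    "GroundTruth", "generate_story", "hrf_signature", "generate_subjects",
    "default_scenario", "centres_in_region",
]

FEATURE_SET_NAMES = ("visual", "syntax", "semantics", "discourse")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``weights[s]`` is subject ``s``'s true ``(V, F, L)`` signature array;
    ``region_masks`` maps each driven feature set to the base-grid voxel
    indices it drives; voxels outside every region have all-zero weights.
    """

    weights: list[np.ndarray]
    region_masks: dict[str, np.ndarray]
    base_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    snr: float
    ar1: float
    noise_sd: list[np.ndarray]
    hrf: np.ndarray
    seed: int
    jitter: list[np.ndarray] = field(default_factory=list)

    @property
    def driven_voxels(self) -> np.ndarray:
        if not self.region_masks:
            return np.array([], dtype=int)
        return np.unique(np.concatenate(list(self.region_masks.values())))


def generate_story(n_words: int, n_features: int = 10, sparsity: float = 0.1,
                   word_period: float = 0.5, seed: int = 0) -> AnnotatedStory:
    """Random RSVP story with named feature sets.

    Column 0 is the word length (letters of the generated token, a positive
    right-skewed "visual" percept); the remaining columns are split into
    syntax / semantics / discourse sets, with semantics continuous
    (gamma-distributed, emulating non-negative sparse embeddings) and the
    discrete sets 0/1 indicators active with probability ``sparsity``.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    if n_features < 2:
        raise ValueError("need n_features >= 2 to form at least two feature sets")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))

    lengths = 1 + rng.poisson(3.5, size=n_words)
    letters = np.array(list(string.ascii_lowercase))
    words = ["".join(rng.choice(letters, size=n)) for n in lengths]
    onsets = np.arange(n_words) * word_period

    feature_names = ["word_length"]
    columns = [annotate_word_length(words)]
    other_sets = [s for s in FEATURE_SET_NAMES if s != "visual"]
    n_other = n_features - 1
    groups = np.array_split(np.arange(n_other), min(len(other_sets), n_other))
    feature_sets: dict[str, list[str]] = {"visual": ["word_length"]}
    for set_name, cols in zip(other_sets, groups):
        members = []
        for j in cols:
            name = f"{set_name}_{j}"
            if set_name == "semantics":
                col = rng.gamma(2.0, 1.0, size=n_words)
            else:
                col = (rng.random(n_words) < sparsity).astype(float)
            feature_names.append(name)
            columns.append(col)
            members.append(name)
        feature_sets[set_name] = members
    return AnnotatedStory(
        words=words, onsets=onsets, features=np.column_stack(columns),
        feature_names=feature_names, feature_sets=feature_sets,
        word_duration=word_period,
    )


def hrf_signature(lag_seconds=(2.0, 4.0, 6.0, 8.0)) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the lags,
    peak-normalized to 1.

    Ground truth for simulation only: the estimator never assumes this (or
    any) response shape.
    """
    lags = np.asarray(lag_seconds, dtype=float)
    if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise ValueError("lag_seconds must be positive and increasing")
    h = sp_stats.gamma.pdf(lags, a=6.0) - sp_stats.gamma.pdf(lags, a=16.0) / 6.0
    return h / np.max(np.abs(h))


def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    """Near-cubic integer factorization nx*ny*nz == n_voxels."""
    best = (n_voxels, 1, 1)
    best_cost = float("inf")
    for nz in range(1, int(round(n_voxels ** (1 / 3))) + 2):
        if n_voxels % nz:
            continue
        rest = n_voxels // nz
        for ny in range(nz, int(np.sqrt(rest)) + 1):
            if rest % ny:
                continue
            nx = rest // ny
            cost = np.ptp([nx, ny, nz])
            if cost < best_cost:
                best_cost = cost
                best = (nx, ny, nz)
    return best


def _ar1_noise(rng: np.random.Generator, T: int, V: int, ar1: float) -> np.ndarray:
    """Stationary unit-variance AR(1) noise, one series per voxel."""
    e = rng.standard_normal((T, V))
    if ar1 == 0:
        return e
    # x_t = ar1 * x_{t-1} + sqrt(1 - ar1^2) * e_t; variance converges to 1
    # within a few samples for moderate ar1
    return sp_signal.lfilter([np.sqrt(1 - ar1**2)], [1.0, -ar1], e, axis=0)


def generate_subjects(story: AnnotatedStory, layout: dict[str, float] | None = None,
                      *, n_subjects: int = 2, snr: float = 1.0,
                      ar1: float = 0.3, jitter_mm: float = 3.0,
                      voxel_size: float = 3.0, n_voxels: int = 200,
                      T: int | None = None, tr: float = 2.0, n_lags: int = 4,
                      seed: int = 0,
                      subject_seeds: list[int] | None = None
                      ) -> tuple[list[SubjectData], GroundTruth]:
    """Simulate multi-subject fMRI from the encoding equation.

    ``layout`` maps feature-set names to the fraction of voxels driven by
    that set (default: semantics and visual drive 25% each, in spatially
    separated slabs of the voxel grid).  Driven voxels receive
    ``signal = lagged features x (amplitude x HRF signature)``; noise is
    stationary AR(1), scaled per driven voxel so that
    ``SD(signal)/SD(noise) = snr``.  ``snr=0`` yields pure noise with no
    feature dependence; ``snr=inf`` is noise-free.  Each subject's voxel grid
    is translated by a random offset up to ``jitter_mm`` per axis, emulating
    small anatomical variations between brains.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    fts = resample_to_tr(story, tr)
    T0 = fts.n_trs
    if T is None:
        T = T0
    if T < 100:
        raise ValueError("T must be >= 100 (the model needs several folds of "
                         "training data)")
    if T > T0:
        raise ValueError(f"story covers only {T0} TRs, cannot simulate T={T}")
    fts.values = fts.values[:T]

    layout = {"semantics": 0.25, "visual": 0.25} if layout is None else layout
    for set_name in layout:
        if set_name not in story.feature_sets:
            raise KeyError(f"layout references unknown feature set {set_name!r}; "
                           f"story defines {sorted(story.feature_sets)}")

    shape = _grid_shape(n_voxels)
    ijk = np.indices(shape).reshape(3, -1).T
    base_coords = ijk.astype(float) * voxel_size

    # compact 3D blobs grown from alternating grid corners, so regions are
    # spatially contiguous and well separated
    corners = [(0, 0, 0), (1, 1, 1), (0, 1, 1), (1, 0, 0),
               (0, 0, 1), (1, 1, 0), (0, 1, 0), (1, 0, 1)]
    extents = np.array(shape) - 1
    region_masks: dict[str, np.ndarray] = {}
    taken = np.zeros(n_voxels, dtype=bool)
    for k, (set_name, frac) in enumerate(sorted(layout.items())):
        count = int(round(frac * n_voxels))
        if count < 1 or taken.sum() + count > n_voxels:
            raise ValueError("layout fractions overflow the voxel grid")
        corner = np.array(corners[k % len(corners)]) * extents
        cheb = np.max(np.abs(ijk - corner), axis=1)
        order = np.lexsort((np.arange(n_voxels), cheb))
        order = order[~taken[order]][:count]
        taken[order] = True
        region_masks[set_name] = np.sort(order)
    all_driven = (np.concatenate(list(region_masks.values()))
                  if region_masks else np.array([], dtype=int))

    lag_seconds = [tr * d for d in range(1, n_lags + 1)]
    hrf = hrf_signature(lag_seconds)
    design = build_lagged_design(fts, n_lags=n_lags)
    F = fts.n_features
    col_of = {name: i for i, name in enumerate(fts.feature_names)}

    subjects, weights_all, noise_sd_all, jitters = [], [], [], []
    for s in range(n_subjects):
        if subject_seeds is not None:
            rng = np.random.default_rng(np.random.SeedSequence([subject_seeds[s], 23]))
        else:
            rng = np.random.default_rng(np.random.SeedSequence([seed, 23, s]))
        W = np.zeros((n_voxels, F, n_lags))
        for set_name, vox in region_masks.items():
            cols = [col_of[m] for m in story.feature_sets[set_name]]
            amps = rng.standard_normal((len(vox), len(cols)))
            W[np.ix_(vox, cols)] = amps[:, :, None] * hrf[None, None, :]
        sig = design.values @ W.reshape(n_voxels, F * n_lags).T
        noise = _ar1_noise(rng, T, n_voxels, ar1)
        noise /= noise.std(axis=0)  # exact unit SD so the requested SNR holds

        driven = np.zeros(n_voxels, dtype=bool)
        driven[all_driven] = True
        sig_sd = sig.std(axis=0)
        noise_sd = np.ones(n_voxels)
        if snr == 0:
            sig = np.zeros_like(sig)
            W = np.zeros_like(W)
        elif np.isinf(snr):
            noise_sd = np.zeros(n_voxels)
        else:
            ok = driven & (sig_sd > 0)
            noise_sd[ok] = sig_sd[ok] / snr
            fill = noise_sd[ok].mean() if ok.any() else 1.0
            noise_sd[~ok] = fill
        observed = sig + noise * noise_sd[None, :]

        offset = (rng.uniform(-jitter_mm, jitter_mm, size=3)
                  if jitter_mm > 0 else np.zeros(3))
        subjects.append(SubjectData(f"sub-{s:02d}", observed,
                                    base_coords + offset, voxel_size))
        weights_all.append(W)
        noise_sd_all.append(noise_sd)
        jitters.append(offset)

    truth = GroundTruth(
        weights=weights_all, region_masks=region_masks,
        base_coords=base_coords, grid_shape=shape, snr=snr, ar1=ar1,
        noise_sd=noise_sd_all, hrf=hrf, seed=seed, jitter=jitters,
    )
    return subjects, truth


def default_scenario(seed: int = 0, *, snr: float = 1.0, T: int = 600,
                     n_voxels: int = 200, n_subjects: int = 2,
                     n_features: int = 10, tr: float = 2.0,
                     word_period: float = 0.5,
                     layout: dict[str, float] | None = None,
                     **kwargs) -> tuple[AnnotatedStory, list[SubjectData], GroundTruth]:
    """Desk-scale study: story + subjects in one seeded call.

    The story is generated just long enough to cover ``T`` TRs at the RSVP
    word rate (4 words per 2 s TR by default).
    """
    n_words = int(np.ceil(T * tr / word_period))
    story = generate_story(n_words, n_features=n_features,
                           word_period=word_period, seed=seed)
    subjects, truth = generate_subjects(
        story, layout, n_subjects=n_subjects, snr=snr, n_voxels=n_voxels,
        T=T, tr=tr, seed=seed, **kwargs,
    )
    return story, subjects, truth


def centres_in_region(truth: GroundTruth, grid: np.ndarray,
                      set_name: str) -> np.ndarray:
    """Boolean mask over grid centres lying on the planted region's voxels
    (base-grid coordinates, half-voxel tolerance)."""
    region = truth.base_coords[truth.region_masks[set_name]]
    region_set = {tuple(np.round(c, 3)) for c in region}
    return np.array([tuple(np.round(c, 3)) in region_set for c in grid])
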