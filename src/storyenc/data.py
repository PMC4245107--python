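"""Per-subject fMRI data: activity matrix plus MNI voxel coordinates.

Subjects are assumed already normalized to MNI space; coordinates are
millimetres under the NIfTI RAS+ voxel-centre convention.  Group analyses
pool voxels across subjects by concatenation — never by averaging — so each
subject keeps its own voxel grid (ventricle size and cortical folding differ
across brains, and small anatomical offsets between subjects are expected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SubjectData"]


@dataclass
class SubjectData:
    """One subject's fMRI run.

    Parameters
    ----------
    subject_id
        Label used in provenance and error messages.
    fmri
        ``(T, V)`` matrix of voxel time series.
    coords
        ``(V, 3)`` MNI millimetre coordinates, one row per voxel column.
    voxel_size
        Isotropic voxel edge length in mm.
    """

    subject_id: str
    fmri: np.ndarray
    coords: np.ndarray
    voxel_size: float = 3.0

    def __post_init__(self) -> None:
        self.fmri = np.atleast_2d(np.asarray(self.fmri, dtype=float))
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape != (self.fmri.shape[1], 3):
            raise ValueError(
                f"coords must be ({self.fmri.shape[1]}, 3); got {self.coords.shape}"
            )
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        uniq = np.unique(np.round(self.coords, 6), axis=0)
        if uniq.shape[0] != self.coords.shape[0]:
            raise ValueError(f"subject {self.subject_id}: duplicate voxel coordinates")

    @property
    def n_trs(self) -> int:
        return self.fmri.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.fmri.shape[1]

    def restrict(self, voxels: np.ndarray) -> "SubjectData":
        """A view of the subject limited to the given voxel indices."""
        voxels = np.asarray(voxels, dtype=int)
        return SubjectData(self.subject_id, self.fmri[:, voxels],
                          self.coords[voxels], self.voxel_size)
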