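"""Jacobian-determinant morphometry and per-lobule feature aggregation.

The Jacobian determinant of a deformation quantifies local volume change:
for a pull-back displacement ``d`` the deformed coordinates are
``(u, v, w) = (x, y, z) + d``, and per voxel

    J = det( d(u, v, w) / d(x, y, z) ) = det( I + grad d )

with the spatial gradient discretized by central differences (one-sided on
the boundary faces).  ``J = 1`` means no volume change, ``J < 1`` shrinkage,
``J > 1`` expansion; ``J <= 0`` indicates folding and is reported, never
silently accepted.

Feature aggregation masks a registered volume (or Jacobian map) with the
split lobule atlas and takes the arithmetic mean per side-specific lobule,
yielding one 70-vector per scan per feature family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .atlas_io import LabeledAtlas

log = logging.getLogger(__name__)

INTENSITY = "intensity"
JACOBIAN = "jacobian"


def jacobian_determinant(disp: np.ndarray) -> np.ndarray:
    """Per-voxel determinant of the Jacobian of a deformation field.

    Parameters
    ----------
    disp : ndarray, shape (nx, ny, nz, 3)
        Pull-back displacement in voxel units on the fixed grid.

    Returns
    -------
    ndarray, shape (nx, ny, nz)
        ``det(I + grad d)``; exactly 1 everywhere for the zero field.
    """
    disp = np.asarray(disp, dtype=np.float64)
    if disp.ndim != 4 or disp.shape[-1] != 3:
        raise ValueError("expected a displacement field of shape (nx, ny, nz, 3)")
    if not np.isfinite(disp).all():
        raise ValueError("displacement field contains NaN or infinite values")

    # G[a][b] = d d_a / d x_b  (central differences, one-sided at boundaries)
    G = [list(np.gradient(disp[..., a])) for a in range(3)]
    for a in range(3):
        G[a][a] = G[a][a] + 1.0  # I + grad d

    det = (
        G[0][0] * (G[1][1] * G[2][2] - G[1][2] * G[2][1])
        - G[0][1] * (G[1][0] * G[2][2] - G[1][2] * G[2][0])
        + G[0][2] * (G[1][0] * G[2][1] - G[1][1] * G[2][0])
    )
    return det


def folding_count(jac: np.ndarray) -> int:
    """Number of voxels with non-positive determinant (local folding)."""
    return int(np.count_nonzero(jac <= 0))


@dataclass
class LobuleMeans:
    """Mean feature value per split lobule label for one scan.

    ``values`` aligns with ``label_ids``; lobules with no voxels are NaN with
    the corresponding ``missing`` flag set (never silently zero).
    """

    label_ids: list[int]
    values: np.ndarray
    family: str
    subject_id: str = ""
    scan_index: int = -1
    day: int = -1

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def value_of(self, label_id: int) -> float:
        return float(self.values[self.label_ids.index(label_id)])


def lobule_means(
    volume: np.ndarray,
    atlas: LabeledAtlas,
    family: str = INTENSITY,
    subject_id: str = "",
    scan_index: int = -1,
    day: int = -1,
) -> LobuleMeans:
    """Arithmetic mean of ``volume`` over each split lobule of the atlas."""
    if not atlas.is_split:
        raise ValueError("atlas must be split left/right before aggregation")
    if volume.shape != atlas.shape:
        raise ValueError("input volume is not on the atlas grid")
    labels = atlas.labels.ravel()
    vals = np.asarray(volume, dtype=np.float64).ravel()
    nmax = labels.max() + 1
    sums = np.bincount(labels, weights=vals, minlength=nmax)
    counts = np.bincount(labels, minlength=nmax)
    out = np.full(len(atlas.split_label_ids), np.nan)
    for i, lid in enumerate(atlas.split_label_ids):
        if lid < nmax and counts[lid] > 0:
            out[i] = sums[lid] / counts[lid]
    n_missing = int(np.count_nonzero(~np.isfinite(out)))
    if n_missing:
        log.warning("%d lobule(s) empty for subject=%s scan=%d", n_missing,
                    subject_id, scan_index)
    return LobuleMeans(
        label_ids=list(atlas.split_label_ids),
        values=out,
        family=family,
        subject_id=subject_id,
        scan_index=scan_index,
        day=day,
    )


def scan_features(
    warped: np.ndarray,
    disp: np.ndarray,
    atlas: LabeledAtlas,
    subject_id: str = "",
    scan_index: int = -1,
    day: int = -1,
) -> tuple[LobuleMeans, LobuleMeans]:
    """Intensity and Jacobian lobule means for one registered scan.

    ``warped`` is the scan resampled into template space; ``disp`` is the
    non-rigid displacement recovered by registration (the affine component is
    deliberately excluded from the Jacobian, so the determinant reflects
    non-rigid shape change only).  Folding voxels are counted and logged.
    """
    jac = jacobian_determinant(disp)
    n_fold = folding_count(jac)
    n_fold_labeled = folding_count(np.where(atlas.labels > 0, jac, 1.0))
    if n_fold_labeled:
        log.warning(
            "subject=%s scan=%d: %d folded voxel(s) inside labeled lobules",
            subject_id, scan_index, n_fold_labeled,
        )
    elif n_fold:
        # extrapolation outside the registration mask may fold; the labeled
        # region (where features are read) is what matters
        log.debug(
            "subject=%s scan=%d: %d folded voxel(s), all outside the atlas",
            subject_id, scan_index, n_fold,
        )
    intens = lobule_means(warped, atlas, INTENSITY, subject_id, scan_index, day)
    jmeans = lobule_means(jac, atlas, JACOBIAN, subject_id, scan_index, day)
    return intens, jmeans
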