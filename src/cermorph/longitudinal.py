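"""Temporal interpolation of sparse lobule means onto a fixed 7-month grid.

Scans arrive at irregular post-operative days, so each subject's 70 lobule
means are linearly interpolated in time and evaluated at seven month-centre
days (day ``30 m - 15`` for month ``m``), giving 70 x 7 = 490 feature values
per subject per family.  Outside a subject's observed day span the nearest
observed value is carried (constant extrapolation: no trend is fabricated).
Subjects with fewer than two scans inside the study window cannot be
interpolated and are excluded with a logged reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import LobuleMeans

log = logging.getLogger(__name__)


class SubjectExclusionError(ValueError):
    """Subject cannot enter the feature grid (fewer than 2 eligible scans)."""


@dataclass
class MonthGrid:
    """The analysis grid: months 1..n_months at centre day ``30 m - 15``."""

    n_months: int = 7
    days_per_month: int = 30
    horizon_days: int = 210

    @property
    def months(self) -> np.ndarray:
        return np.arange(1, self.n_months + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.days_per_month * self.months - self.days_per_month // 2


@dataclass
class FeatureMatrix:
    """Subjects x (lobules x months) feature matrix for one family.

    Columns are ordered label-major, month-minor; ``columns[j]`` is the
    ``(split label id, month)`` pair of column ``j`` and the mapping is
    invertible via :meth:`column_of`.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]
    columns: list[tuple[int, int]]
    family: str
    _index: dict[tuple[int, int], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.subject_ids), len(self.columns)):
            raise ValueError("feature matrix shape does not match its index")
        if len(self.y) != len(self.subject_ids):
            raise ValueError("outcome vector misaligned with rows")
        self._index = {lm: j for j, lm in enumerate(self.columns)}

    def column_of(self, label_id: int, month: int) -> int:
        return self._index[(label_id, month)]

    def decode(self, column: int) -> tuple[int, int]:
        if not 0 <= column < len(self.columns):
            raise IndexError(f"column {column} out of range")
        return self.columns[column]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        cols = [f"{l}_{m}" for l, m in self.columns]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "outcome", self.y)
        df.insert(0, "subject", self.subject_ids)
        df.to_csv(path, index=False)
        return path

    def column_map_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {str(j): {"label": int(l), "month": int(m)}
                 for j, (l, m) in enumerate(self.columns)},
                indent=2,
            )
        )
        return path


def interpolate_subject(
    means: list[LobuleMeans], grid: MonthGrid = MonthGrid()
) -> np.ndarray:
    """Interpolate one subject's per-scan lobule means onto the month grid.

    Parameters
    ----------
    means : list of LobuleMeans
        One entry per scan, each carrying its acquisition day; all must share
        one label set and family.
    grid : MonthGrid

    Returns
    -------
    ndarray, shape (n_lobules, n_months)
        Piecewise-linear interpolation at the month centres with constant
        extrapolation outside the observed span; every cell finite.

    Raises
    ------
    SubjectExclusionError
        If fewer than two scans fall inside ``[1, horizon_days]``.
    """
    eligible = sorted(
        (m for m in means if 1 <= m.day <= grid.horizon_days), key=lambda m: m.day
    )
    if len(eligible) < 2:
        sid = means[0].subject_id if means else "?"
        log.info(
            "excluding subject %s: %d scan(s) in the %d-day window (need 2)",
            sid, len(eligible), grid.horizon_days,
        )
        raise SubjectExclusionError(
            f"subject {sid}: fewer than 2 scans within the study window"
        )
    label_ids = eligible[0].label_ids
    if any(m.label_ids != label_ids for m in eligible):
        raise ValueError("inconsistent label sets across scans")
    days = np.asarray([m.day for m in eligible], dtype=np.float64)
    values = np.stack([m.values for m in eligible], axis=1)  # (L, S)
    out = np.empty((len(label_ids), grid.n_months))
    centers = grid.centers.astype(np.float64)
    for i in range(len(label_ids)):
        # np.interp is piecewise linear with constant end extrapolation
        out[i] = np.interp(centers, days, values[i])
    if not np.isfinite(out).all():
        raise ValueError("non-finite lobule means cannot be interpolated")
    return out


def build_feature_matrix(
    per_subject: dict[str, np.ndarray],
    outcomes: dict[str, int],
    label_ids: list[int],
    family: str,
    grid: MonthGrid = MonthGrid(),
) -> FeatureMatrix:
    """Assemble interpolated per-subject blocks into one feature matrix.

    ``per_subject`` maps subject id to its (n_lobules, n_months) block from
    :func:`interpolate_subject`; rows are sorted by subject id so every
    family built from the same cohort shares one row ordering.
    """
    sids = sorted(per_subject)
    columns = [(l, int(m)) for l in label_ids for m in grid.months]
    n_l, n_m = len(label_ids), grid.n_months
    X = np.empty((len(sids), n_l * n_m))
    for i, sid in enumerate(sids):
        block = per_subject[sid]
        if block.shape != (n_l, n_m):
            raise ValueError(
                f"subject {sid}: block shape {block.shape} != ({n_l}, {n_m})"
            )
        X[i] = block.ravel()
    y = np.asarray([outcomes[sid] for sid in sids], dtype=int)
    return FeatureMatrix(
        X=X, y=y, subject_ids=sids, columns=columns, family=family
    )
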