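"""Volume I/O, intensity normalization, and the left/right-split lobule label space.

The analysis operates on a labeled cerebellum/brain-stem atlas: a template
intensity volume plus an integer parcellation that is mirror-symmetric about
the mid-sagittal voxel plane (35 symmetric lobule labels by default).  To
localize findings by hemisphere the symmetric parcellation is *split*: voxels
on the anatomical left keep-shifted ids (``symmetric id + LEFT_STRIDE``) while
right-side voxels keep the original id, giving 70 side-specific labels.

Arrays are indexed (x, y, z) with x running anatomical left -> right,
y posterior -> anterior, z inferior -> superior (RAS+ world axes).  The
mid-sagittal plane is voxel column ``nx // 2``; for odd ``nx`` the plane
column itself counts as right.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np

#: Offset added to a symmetric label id to form its left-hemisphere split id.
#: A stride of 100 cannot collide for parcellations of <= 99 symmetric labels.
LEFT_STRIDE = 100

RIGHT = "right"
LEFT = "left"


class VolumeShapeError(ValueError):
    """Raised for non-3D volumes or grid mismatches."""


class DegenerateRangeError(ValueError):
    """Raised when an image has no usable intensity range."""


class ScheduleError(ValueError):
    """Raised for malformed acquisition-schedule tables."""


@dataclass
class LabeledAtlas:
    """Template intensity volume plus its (possibly split) integer parcellation.

    Parameters
    ----------
    template : ndarray, shape (nx, ny, nz)
        Smooth intensity template; zero outside the structure.
    labels : ndarray of int, same shape
        Parcellation.  Before splitting it holds the symmetric label ids;
        after :func:`split_atlas_left_right` it holds side-specific ids.
    voxel_to_world : ndarray, shape (4, 4)
        RAS+ affine of both volumes.
    symmetric_label_ids : list of int
        Distinct non-zero symmetric ids.
    split_label_ids : list of int
        Side-specific ids (empty until the atlas has been split).
    split_map : dict
        ``(symmetric id, side) -> split id`` for every side that has voxels.
    """

    template: np.ndarray
    labels: np.ndarray
    voxel_to_world: np.ndarray
    symmetric_label_ids: list[int]
    split_label_ids: list[int] = field(default_factory=list)
    split_map: dict[tuple[int, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.template.shape != self.labels.shape:
            raise VolumeShapeError("template and labels must share one grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeShapeError("labels must be an integer volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.template.shape

    @property
    def is_split(self) -> bool:
        return bool(self.split_label_ids)

    def lobule_mask(self, split_id: int) -> np.ndarray:
        return self.labels == split_id

    def side_of(self, split_id: int) -> str:
        return LEFT if split_id > LEFT_STRIDE else RIGHT

    def symmetric_id_of(self, split_id: int) -> int:
        return split_id - LEFT_STRIDE if split_id > LEFT_STRIDE else split_id


@dataclass
class ScanRecord:
    """One acquired volume with its acquisition day (days after surgery)."""

    subject_id: str
    scan_index: int
    day: int
    volume: np.ndarray | None = None


@dataclass
class SubjectSeries:
    """Ordered per-subject scan collection with the binary outcome label."""

    subject_id: str
    outcome: int
    scans: list[ScanRecord]

    def __post_init__(self) -> None:
        days = [s.day for s in self.scans]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ScheduleError(
                f"subject {self.subject_id}: scan days must strictly increase"
            )

    @property
    def days(self) -> list[int]:
        return [s.day for s in self.scans]


# ---------------------------------------------------------------------------
# volume I/O


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI-1 volume.  Returns ``(data, affine)``; rejects 4D files."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume not found: {path}")
    img = nib.load(path)
    if img.ndim != 3:
        raise VolumeShapeError(f"{path}: expected a 3D volume, got {img.ndim}D")
    data = np.asarray(img.dataobj)
    return data, img.affine


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(data, affine), path)
    return path


# ---------------------------------------------------------------------------
# intensity normalization


def _robust_range(vol: np.ndarray) -> tuple[float, float]:
    nz = vol[vol != 0]
    if nz.size == 0:
        raise DegenerateRangeError("volume has no non-zero voxels")
    lo, hi = np.percentile(nz, [1.0, 99.0])
    if hi <= lo:
        raise DegenerateRangeError("volume intensity range is degenerate")
    return float(lo), float(hi)


def normalize_intensity(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Linearly map the image's robust intensity range onto the template's.

    The robust range is the 1st-99th percentile of non-zero voxels, so a
    handful of hot voxels cannot skew the mapping.  The map is affine and
    order-preserving; applying it twice is a no-op (to float precision).
    """
    ilo, ihi = _robust_range(image)
    tlo, thi = _robust_range(template)
    scale = (thi - tlo) / (ihi - ilo)
    out = (np.asarray(image, dtype=np.float64) - ilo) * scale + tlo
    out[image == 0] = 0.0  # keep the background exact
    return out


# ---------------------------------------------------------------------------
# left/right label split


def mid_sagittal_column(nx: int) -> int:
    return nx // 2


def split_atlas_left_right(atlas: LabeledAtlas) -> LabeledAtlas:
    """Split a symmetric parcellation into side-specific labels.

    Voxels strictly left of the mid-sagittal plane (x < nx // 2) are remapped
    to ``id + LEFT_STRIDE``; the plane itself and everything right of it keep
    the symmetric id.  A 35-label symmetric atlas with every label present on
    both sides therefore yields 70 split labels.  Labels confined to a single
    side are recorded once in ``split_map`` (with a warning via the missing
    side simply absent).
    """
    if atlas.is_split:
        raise ValueError("atlas labels are already split")
    labels = atlas.labels
    nx = labels.shape[0]
    left = np.zeros_like(labels, dtype=bool)
    left[: mid_sagittal_column(nx)] = True

    split = labels.copy()
    split[left & (labels > 0)] += LEFT_STRIDE

    split_map: dict[tuple[int, str], int] = {}
    split_ids: list[int] = []
    for sym in atlas.symmetric_label_ids:
        if np.any(split == sym):
            split_map[(sym, RIGHT)] = sym
            split_ids.append(sym)
        if np.any(split == sym + LEFT_STRIDE):
            split_map[(sym, LEFT)] = sym + LEFT_STRIDE
            split_ids.append(sym + LEFT_STRIDE)
    return LabeledAtlas(
        template=atlas.template,
        labels=split,
        voxel_to_world=atlas.voxel_to_world,
        symmetric_label_ids=list(atlas.symmetric_label_ids),
        split_label_ids=split_ids,
        split_map=split_map,
    )


def merge_split_labels(atlas: LabeledAtlas) -> np.ndarray:
    """Undo the left/right split, returning the symmetric label volume."""
    merged = atlas.labels.copy()
    merged[merged > LEFT_STRIDE] -= LEFT_STRIDE
    return merged


# ---------------------------------------------------------------------------
# acquisition schedules

SCHEDULE_HEADER = ["subject", "scan", "days_after_surgery", "outcome"]


def load_schedule(csv_path: str | Path) -> list[SubjectSeries]:
    """Parse a schedule CSV (``subject,scan,days_after_surgery,outcome``).

    Returns one metadata-only :class:`SubjectSeries` per subject, scans sorted
    by day.  Duplicate (subject, day) rows and non-binary outcomes are
    rejected.  Negative days (pre-operative scans) are allowed here; the
    post-operative restriction is applied downstream by the feature grid.
    """
    csv_path = Path(csv_path)
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            f.strip() for f in reader.fieldnames
        ] != SCHEDULE_HEADER:
            raise ScheduleError(
                f"{csv_path}: expected header {','.join(SCHEDULE_HEADER)}"
            )
        rows = list(reader)

    by_subject: dict[str, list[tuple[int, int]]] = {}
    outcomes: dict[str, int] = {}
    for row in rows:
        sid = row["subject"].strip()
        day = int(row["days_after_surgery"])
        outcome = row["outcome"].strip()
        if outcome not in ("0", "1"):
            raise ScheduleError(f"{csv_path}: non-binary outcome {outcome!r}")
        if sid in outcomes and outcomes[sid] != int(outcome):
            raise ScheduleError(f"{csv_path}: inconsistent outcome for {sid}")
        outcomes[sid] = int(outcome)
        by_subject.setdefault(sid, []).append((day, int(row["scan"])))

    series = []
    for sid in by_subject:
        entries = sorted(by_subject[sid])
        days = [d for d, _ in entries]
        if len(set(days)) != len(days):
            raise ScheduleError(f"{csv_path}: duplicate (subject, day) for {sid}")
        scans = [
            ScanRecord(subject_id=sid, scan_index=i, day=d)
            for i, (d, _) in enumerate(entries)
        ]
        series.append(SubjectSeries(subject_id=sid, outcome=outcomes[sid], scans=scans))
    series.sort(key=lambda s: s.subject_id)
    return series


@dataclass
class ReferenceSeries:
    """One patient of the printed reference schedule (days may repeat:
    a day-of-surgery scan and an intra-operative scan are both day 0)."""

    subject_id: str
    outcome: int
    days: list[int]


def reference_schedule() -> list[ReferenceSeries]:
    """The 40-patient reference acquisition schedule shipped with the package.

    Days are days after posterior-fossa surgery; negative values are
    pre-operative scans and 0 marks day-of-surgery / intra-operative scans.
    Seven of the forty patients carry a positive mutism-syndrome outcome.
    """
    with resources.files("cermorph.data").joinpath("reference_schedule.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    by_subject: dict[str, list[int]] = {}
    outcomes: dict[str, int] = {}
    for row in rows:
        sid = row["subject"]
        by_subject.setdefault(sid, []).append(int(row["days_after_surgery"]))
        outcomes[sid] = int(row["outcome"])
    return [
        ReferenceSeries(sid, outcomes[sid], sorted(by_subject[sid]))
        for sid in sorted(by_subject, key=int)
    ]


def schedule_statistics(series, min_day: int = 0) -> dict[str, float]:
    """Per-patient scan-count and inter-scan-gap summary of a schedule.

    Only scans acquired on or after ``min_day`` are counted (default 0:
    everything from the day of surgery onward; pre-operative scans are not
    acquisitions of the post-surgical follow-up).  Gaps are differences
    between consecutive counted scans within a patient.
    """
    counts, gaps = [], []
    for s in series:
        days = [d for d in s.days if d >= min_day]
        counts.append(len(days))
        gaps.extend(np.diff(days))
    gaps = np.asarray(gaps, dtype=float)
    return {
        "mean_scans": float(np.mean(counts)),
        "sd_scans": float(np.std(counts, ddof=1)),
        "mean_gap_days": float(np.mean(gaps)),
        "sd_gap_days": float(np.std(gaps, ddof=1)),
        "n_patients": len(series),
        "n_gaps": int(gaps.size),
    }
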