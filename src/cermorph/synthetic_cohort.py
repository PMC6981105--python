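"""Self-contained synthetic cohort generator with planted ground-truth effects.

Emulates the statistical structure of a longitudinal post-operative imaging
cohort: 40 subjects (7 with a positive mutism-syndrome outcome), 2-5 scans
per subject at irregular intervals, a 35-label mirror-symmetric cerebellum
parcellation, and group-specific planted effects confined to chosen
lobule x month windows:

* *intensity* effects add a constant grey-level offset inside one lobule
  during its active months;
* *deformation* effects apply a local isotropic scaling of factor ``s``
  centred on the lobule centroid and feathered to zero at the lobule
  boundary, so the true Jacobian determinant in the lobule core is ``s**3``.

Each scan is the template warped by a smooth subject-specific deformation
(low-order DCT field) plus a small random affine, with additive acquisition
noise.  Everything is reproducible bit-for-bit from the config seed, and the
ground truth (outcomes, planted effects, per-scan deformation parameters) is
returned alongside the images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt

from .atlas_io import (
    LabeledAtlas,
    ScanRecord,
    SubjectSeries,
    mid_sagittal_column,
    save_volume,
    split_atlas_left_right,
)
from .registration import (
    AffineTransform,
    apply_affine,
    apply_deformation,
    dct_basis,
    invert_deformation,
)

MONTH_DAYS = 30

INTENSITY = "intensity"
DEFORMATION = "deformation"


class CohortSizingError(ValueError):
    """Raised when the grid cannot host the requested parcellation."""


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the reference cohort: 40 subjects, 7 positive outcomes,
    a mean of 4 +/- 1 scans per subject (2-5), inter-scan gaps drawn from a
    truncated normal (mean 109 d, sd 62 d, min 14 d) and compressed into the
    210-day (7-month) post-operative study window when the draw overruns it.
    """

    n_subjects: int = 40
    n_positive: int = 7
    grid_shape: tuple[int, int, int] = (48, 48, 40)
    n_labels_symmetric: int = 35
    scans_mean: float = 4.0
    scans_sd: float = 1.0
    scans_min: int = 2
    scans_max: int = 5
    gap_mean_days: float = 109.0
    gap_sd_days: float = 62.0
    gap_min_days: int = 14
    first_scan_window: tuple[int, int] = (1, 30)
    horizon_days: int = 210
    noise_sd: float = 5.0
    rician_noise: bool = False
    subject_warp_max_voxels: float = 1.2
    subject_warp_order: int = 4
    affine_rot_sd_deg: float = 1.0
    affine_logscale_sd: float = 0.01
    affine_shear_sd: float = 0.005
    affine_shift_sd_voxels: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.n_positive < self.n_subjects):
            raise ValueError("need n_positive < n_subjects")
        if min(self.grid_shape) < 16:
            raise CohortSizingError("grid_shape entries must be >= 16")
        if self.scans_min < 2:
            raise ValueError("subjects need at least 2 scans")
        if self.n_labels_symmetric < 1:
            raise ValueError("need at least one symmetric label")


@dataclass
class PlantedEffect:
    """A group-specific effect confined to one lobule and a month window.

    ``magnitude`` is an additive grey-level offset for the intensity family,
    or the isotropic scale factor ``s`` (> 0, core Jacobian ``s**3``) for the
    deformation family.  ``lobule_id`` is a *split* (side-specific) label.
    """

    family: str
    lobule_id: int
    month_window: tuple[int, ...]
    magnitude: float

    def __post_init__(self) -> None:
        if self.family not in (INTENSITY, DEFORMATION):
            raise ValueError(f"unknown effect family {self.family!r}")
        if not self.month_window:
            raise ValueError("month_window must be non-empty")
        if any(m < 1 or m > 7 for m in self.month_window):
            raise ValueError("months must lie in 1..7")
        if self.family == DEFORMATION and self.magnitude <= 0:
            raise ValueError("deformation scale factor must be positive")


@dataclass
class GroundTruth:
    """Everything needed to check recovery: labels, effects, true warps."""

    outcomes: dict[str, int]
    effects: list[PlantedEffect]
    scan_params: dict[str, list[dict]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "outcomes": self.outcomes,
            "effects": [asdict(e) for e in self.effects],
            "scan_params": self.scan_params,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def month_of_day(day: int) -> int:
    """Post-operative month (1-7) containing an acquisition day >= 1."""
    return min(7, (day - 1) // MONTH_DAYS + 1)


# ---------------------------------------------------------------------------
# atlas generation


def generate_atlas(config: CohortConfig) -> LabeledAtlas:
    """Synthesize a mirror-symmetric labeled atlas on the config grid.

    The template is a smooth, textured ellipsoid ("cerebellum") on a zero
    background; the parcellation divides it into ``n_labels_symmetric``
    radial-shell x angular-sector parcels computed on the right half and
    mirrored across the mid-sagittal voxel plane, so the label volume equals
    its own mirror image exactly and every label has voxels on both sides.
    """
    config.validate()
    nx, ny, nz = config.grid_shape
    n_sym = config.n_labels_symmetric

    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax_, ay, az = 0.42 * nx, 0.40 * ny, 0.38 * nz
    X, Y, Z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    # use |x - cx| so every intensity/label formula is mirror-symmetric
    xi = np.abs(X - cx)
    r = np.sqrt((xi / ax_) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2)
    inside = r <= 1.0

    phi = np.arctan2(Z - cz, Y - cy)  # angle in the sagittal plane
    # intensity tapers smoothly to zero at the boundary so that resampled
    # copies share the template's grey-level distribution (robust-percentile
    # normalization stays consistent across warped scans)
    template = np.where(
        inside,
        (1.0 - r**2)
        * (
            120.0
            + 25.0 * np.cos(4 * np.pi * r)
            + 18.0 * np.cos(3 * phi) * np.sin(2 * np.pi * xi / max(ax_, 1.0))
        ),
        0.0,
    )

    # compact Voronoi parcels on the right half (Lloyd iterations on voxel
    # coordinates), mirrored across the mid-sagittal plane: parcels are
    # chunky enough to host feathered effect cores, unlike thin radial shells
    mid = mid_sagittal_column(nx)
    right = X >= mid
    pts = np.argwhere(inside & right).astype(np.float64)
    if pts.shape[0] < 8 * n_sym:
        raise CohortSizingError("grid too small to host the parcellation")
    seed_rng = np.random.default_rng(1234)  # atlas geometry is config-free
    centers = pts[seed_rng.choice(pts.shape[0], size=n_sym, replace=False)]
    for _ in range(12):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for k in range(n_sym):
            sel = assign == k
            if sel.any():
                centers[k] = pts[sel].mean(axis=0)
            else:  # reseed an empty cell at the worst-covered voxel
                centers[k] = pts[d2.min(axis=1).argmax()]

    labels = np.zeros(config.grid_shape, dtype=np.int32)
    labels[tuple(pts.astype(int).T)] = assign + 1

    # mirror the right half onto the left for exact symmetry
    flipped = labels[::-1]
    labels = np.where(right, labels, flipped)

    ids = sorted(int(v) for v in np.unique(labels) if v != 0)
    if len(ids) != n_sym:
        raise CohortSizingError(
            f"grid too small: only {len(ids)} of {n_sym} parcels are non-empty"
        )
    # every label must appear on both sides of the plane
    for lid in ids:
        m = labels == lid
        if not (m[:mid].any() and m[mid:].any()):
            raise CohortSizingError(f"label {lid} has no voxels on both sides")

    return LabeledAtlas(
        template=template,
        labels=labels,
        voxel_to_world=np.eye(4),
        symmetric_label_ids=ids,
    )


def generate_probability_map(config: CohortConfig) -> np.ndarray:
    """True posterior-probability map of the synthetic structure.

    A smooth logistic ramp in the normalized ellipsoid radius: ~1 well
    inside, 0.5 on the surface, ~0 outside, so thresholding at p > 0.5
    recovers the structure support.
    """
    nx, ny, nz = config.grid_shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax_, ay, az = 0.42 * nx, 0.40 * ny, 0.38 * nz
    X, Y, Z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    r = np.sqrt(
        ((np.abs(X - cx)) / ax_) ** 2
        + ((Y - cy) / ay) ** 2
        + ((Z - cz) / az) ** 2
    )
    return 1.0 / (1.0 + np.exp((r - 1.0) / 0.05))


# ---------------------------------------------------------------------------
# planted deformation fields


def _lobule_core_geometry(
    atlas: LabeledAtlas, lobule_id: int
) -> tuple[np.ndarray, float]:
    """Deepest interior point of a lobule and its inscribed radius."""
    mask = atlas.lobule_mask(lobule_id)
    if not mask.any():
        raise ValueError(f"lobule {lobule_id} has no voxels")
    depth = distance_transform_edt(mask)
    c = np.unravel_index(depth.argmax(), depth.shape)
    return np.asarray(c, dtype=np.float64), float(depth.max())


def local_scaling_field(
    atlas: LabeledAtlas, lobule_id: int, scale: float, feather_voxels: float = 6.0
) -> np.ndarray:
    """Displacement field of a local isotropic scaling centred in one lobule.

    ``d(x) = (s - 1) * (x - c) * w(|x - c|)`` with ``c`` the lobule's deepest
    interior point and ``w`` a radial smoothstep: 1 inside the core sphere
    (radius = the lobule's inscribed radius), falling to 0 over
    ``feather_voxels`` beyond it.  Inside the core the field is an exact
    isotropic scaling, so the Jacobian determinant there is ``s**3``.  The
    compensating contraction lives in the feather shell *outside* the
    lobule: feathering to zero at the lobule boundary itself would pin the
    boundary and force the lobule-mean determinant to 1 (no net volume
    change), erasing the very signal the effect is meant to plant.
    """
    c, r0 = _lobule_core_geometry(atlas, lobule_id)
    grid = np.stack(
        np.meshgrid(*[np.arange(n) for n in atlas.shape], indexing="ij"), axis=-1
    ).astype(np.float64)
    rho = np.sqrt(((grid - c) ** 2).sum(axis=-1))
    t = np.clip((rho - r0) / feather_voxels, 0.0, 1.0)
    w = 1.0 - t * t * (3 - 2 * t)  # smoothstep down from 1 to 0
    return (scale - 1.0) * (grid - c) * w[..., None]


def effect_core_mask(
    atlas: LabeledAtlas, lobule_id: int, feather_voxels: float = 6.0
) -> np.ndarray:
    """Voxels where a planted scaling acts at full strength (the core sphere)."""
    c, r0 = _lobule_core_geometry(atlas, lobule_id)
    grid = np.stack(
        np.meshgrid(*[np.arange(n) for n in atlas.shape], indexing="ij"), axis=-1
    ).astype(np.float64)
    rho = np.sqrt(((grid - c) ** 2).sum(axis=-1))
    return rho <= r0


def _subject_warp(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random smooth subject-specific deformation as a low-order DCT field."""
    K = config.subject_warp_order
    shape = config.grid_shape
    decay = 1.0 / (
        1.0
        + np.add.outer(np.add.outer(np.arange(K), np.arange(K)), np.arange(K))
    )
    coeffs = rng.standard_normal((3, K, K, K)) * decay
    bases = [dct_basis(n, K)[0] for n in shape]
    d = np.einsum("cijk,xi,yj,zk->xyzc", coeffs, *bases, optimize=True)
    peak = np.abs(d).max()
    target = rng.uniform(0.4, 1.0) * config.subject_warp_max_voxels
    if peak > 0:
        d *= target / peak
        coeffs *= target / peak
    return d, coeffs


def _random_affine(
    config: CohortConfig, rng: np.random.Generator
) -> AffineTransform:
    """Small random acquisition pose: rotation, scale, shear, shift."""
    ang = np.deg2rad(rng.normal(0, config.affine_rot_sd_deg, size=3))
    Rs = []
    for axis, a in enumerate(ang):
        R = np.eye(3)
        i, j = [k for k in range(3) if k != axis]
        R[i, i] = R[j, j] = np.cos(a)
        R[i, j], R[j, i] = -np.sin(a), np.sin(a)
        Rs.append(R)
    A = Rs[0] @ Rs[1] @ Rs[2]
    A = A @ np.diag(np.exp(rng.normal(0, config.affine_logscale_sd, size=3)))
    S = np.eye(3)
    S[0, 1], S[0, 2], S[1, 2] = rng.normal(0, config.affine_shear_sd, size=3)
    A = A @ S
    t = rng.normal(0, config.affine_shift_sd_voxels, size=3)
    shape = np.asarray(config.grid_shape, dtype=np.float64)
    c = (shape - 1) / 2
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = t + c - A @ c
    return AffineTransform(m)


# ---------------------------------------------------------------------------
# schedules and series


def draw_scan_days(config: CohortConfig, rng: np.random.Generator) -> list[int]:
    """Draw an irregular post-operative acquisition schedule.

    Scan count ~ round(N(scans_mean, scans_sd)) clipped to [scans_min,
    scans_max]; first scan uniform in ``first_scan_window``; gaps from a
    truncated normal (>= gap_min_days).  If the drawn series overruns the
    study horizon the gap vector is rescaled to fit, preserving the scan
    count; days are integers, strictly increasing, within [1, horizon].
    """
    n = int(np.clip(round(rng.normal(config.scans_mean, config.scans_sd)),
                    config.scans_min, config.scans_max))
    first = int(rng.integers(config.first_scan_window[0],
                             config.first_scan_window[1] + 1))
    gaps = []
    for _ in range(n - 1):
        g = rng.normal(config.gap_mean_days, config.gap_sd_days)
        for _ in range(100):
            if g >= config.gap_min_days:
                break
            g = rng.normal(config.gap_mean_days, config.gap_sd_days)
        gaps.append(max(g, config.gap_min_days))
    gaps = np.asarray(gaps, dtype=np.float64)
    span = gaps.sum()
    budget = config.horizon_days - first
    if span > budget:
        gaps *= budget / span
    days = first + np.concatenate([[0.0], np.cumsum(gaps)])
    days = np.round(days).astype(int)
    for i in range(1, len(days)):  # enforce strict increase after rounding
        days[i] = max(days[i], days[i - 1] + 1)
    days = np.minimum(days, config.horizon_days)
    for i in range(len(days) - 2, -1, -1):
        days[i] = min(days[i], days[i + 1] - 1)
    if days[0] < 1 or len(days) < 2:
        raise RuntimeError("could not draw a valid schedule")  # pragma: no cover
    return [int(d) for d in days]


def generate_subject_series(
    config: CohortConfig,
    atlas: LabeledAtlas,
    subject_id: str,
    outcome: int,
    effects: list[PlantedEffect],
    rng: np.random.Generator,
) -> tuple[SubjectSeries, list[dict]]:
    """Generate one subject's longitudinal scans with planted effects.

    Negative-outcome subjects must carry no effects.  Returns the series and
    the per-scan true deformation parameters for the ground-truth record.
    """
    if outcome == 0 and effects:
        raise ValueError("effects must be empty for negative-outcome subjects")
    days = draw_scan_days(config, rng)
    d_subj, subj_coeffs = _subject_warp(config, rng)

    # deformation-effect fields depend only on the atlas, compute once
    eff_fields = {
        id(e): local_scaling_field(atlas, e.lobule_id, e.magnitude)
        for e in effects
        if e.family == DEFORMATION
    }
    # scans sharing the same active deformation effects share one inverse
    inv_cache: dict[tuple, np.ndarray] = {}

    scans: list[ScanRecord] = []
    params: list[dict] = []
    for idx, day in enumerate(days):
        month = month_of_day(day)
        active = [e for e in effects if month in e.month_window]

        vol = atlas.template
        for e in active:
            if e.family == INTENSITY:
                vol = vol + e.magnitude * atlas.lobule_mask(e.lobule_id)

        active_def = tuple(
            sorted(id(e) for e in active if e.family == DEFORMATION)
        )
        d_true = d_subj.copy()
        for eid in active_def:
            d_true = d_true + eff_fields[eid]

        affine = _random_affine(config, rng)
        if np.abs(d_true).max() > 0:
            if active_def not in inv_cache:
                inv_cache[active_def] = invert_deformation(d_true)
            scan = apply_deformation(vol, inv_cache[active_def])
        else:
            scan = np.asarray(vol, dtype=np.float64).copy()
        if not np.allclose(affine.matrix, np.eye(4)):
            scan = apply_affine(scan, affine)

        if config.noise_sd > 0:
            noise = rng.normal(0, config.noise_sd, size=scan.shape)
            if config.rician_noise:
                noise2 = rng.normal(0, config.noise_sd, size=scan.shape)
                scan = np.sqrt((scan + noise) ** 2 + noise2**2)
            else:
                scan = scan + noise

        scans.append(ScanRecord(subject_id, idx, day, scan))
        params.append(
            {
                "day": day,
                "month": month,
                "affine_params": affine.params.tolist(),
                "subject_warp_coeffs_shape": list(subj_coeffs.shape),
                "active_effects": [
                    {"family": e.family, "lobule_id": e.lobule_id,
                     "magnitude": e.magnitude}
                    for e in active
                ],
            }
        )
    return SubjectSeries(subject_id, outcome, scans), params


def default_effects(
    atlas: LabeledAtlas,
    rng: np.random.Generator,
    noise_sd: float,
    intensity_factor: float = 2.0,
    deformation_scale: float = 1.15,
    min_core_voxels: int = 20,
) -> list[PlantedEffect]:
    """The default planted-effect pair used by end-to-end recovery studies.

    One intensity effect (offset = ``intensity_factor * noise_sd``) active in
    months 1-3 and one deformation effect (core Jacobian ``s**3``) in months
    5-7, each in a distinct randomly chosen lobule large enough to have a
    feathered core.
    """
    eligible = [
        lid
        for lid in atlas.split_label_ids
        if effect_core_mask(atlas, lid).sum() >= min_core_voxels
    ]
    if len(eligible) < 2:
        raise CohortSizingError("no lobules large enough to plant effects in")
    pick = rng.choice(len(eligible), size=2, replace=False)
    return [
        PlantedEffect(INTENSITY, int(eligible[pick[0]]), (1, 2, 3),
                      intensity_factor * noise_sd),
        PlantedEffect(DEFORMATION, int(eligible[pick[1]]), (5, 6, 7),
                      deformation_scale),
    ]


def generate_cohort(
    config: CohortConfig,
    effects: list[PlantedEffect] | None = None,
) -> tuple[list[SubjectSeries], LabeledAtlas, GroundTruth]:
    """Generate the full cohort: split atlas, subject series, ground truth.

    Deterministic for a fixed ``config.seed`` (bit-identical volumes).  The
    planted effects (default: :func:`default_effects`) are applied only to
    the ``n_positive`` positive-outcome subjects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    atlas = split_atlas_left_right(generate_atlas(config))
    if effects is None:
        effects = (
            default_effects(atlas, rng, config.noise_sd)
            if config.n_positive > 0
            else []
        )

    outcome_vec = np.zeros(config.n_subjects, dtype=int)
    pos = rng.choice(config.n_subjects, size=config.n_positive, replace=False)
    outcome_vec[pos] = 1

    series: list[SubjectSeries] = []
    truth = GroundTruth(outcomes={}, effects=list(effects))
    for i in range(config.n_subjects):
        sid = f"S{i:03d}"
        out = int(outcome_vec[i])
        s, params = generate_subject_series(
            config, atlas, sid, out, effects if out else [], rng
        )
        series.append(s)
        truth.outcomes[sid] = out
        truth.scan_params[sid] = params
    return series, atlas, truth


# ---------------------------------------------------------------------------
# persistence


def write_cohort(
    series: list[SubjectSeries],
    atlas: LabeledAtlas,
    truth: GroundTruth,
    out_dir: str | Path,
    config: CohortConfig | None = None,
) -> dict:
    """Write a cohort to disk: NIfTI volumes, schedule CSV, ground truth.

    Layout: ``template.nii.gz``, ``labels.nii.gz``, ``pmap.nii.gz`` (if a
    config is given), per-scan volumes under ``scans/``, ``schedule.csv``
    with header ``subject,scan,days_after_surgery,outcome`` and
    ``ground_truth.json``.  Returns a manifest of all written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = atlas.voxel_to_world
    manifest: dict = {"scans": {}}
    manifest["template"] = str(save_volume(atlas.template, aff, out_dir / "template.nii.gz"))
    manifest["labels"] = str(
        save_volume(atlas.labels.astype(np.int32), aff, out_dir / "labels.nii.gz")
    )
    if config is not None:
        manifest["pmap"] = str(
            save_volume(generate_probability_map(config), aff, out_dir / "pmap.nii.gz")
        )

    rows = ["subject,scan,days_after_surgery,outcome"]
    for s in series:
        paths = []
        for scan in s.scans:
            p = out_dir / "scans" / f"{s.subject_id}_scan{scan.scan_index:02d}.nii.gz"
            save_volume(np.asarray(scan.volume, dtype=np.float32), aff, p)
            paths.append(str(p))
            rows.append(
                f"{s.subject_id},{scan.scan_index},{scan.day},{s.outcome}"
            )
        manifest["scans"][s.subject_id] = paths
    (out_dir / "schedule.csv").write_text("\n".join(rows) + "\n")
    manifest["schedule"] = str(out_dir / "schedule.csv")
    manifest["ground_truth"] = str(truth.to_json(out_dir / "ground_truth.json"))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["manifest"] = str(out_dir / "manifest.json")
    return manifest
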