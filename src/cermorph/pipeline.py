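"""End-to-end orchestration: synthesize -> validate -> register -> featurize
-> select -> validate-by-ROC -> map, as resumable, logged stages.

The in-memory API (:func:`featurize_scan`, :func:`cohort_feature_matrices`)
carries a cohort from raw volumes to the two 490-column feature matrices;
the stage functions wrap it with file I/O, a manifest (config hash, derived
seeds, per-stage wall time, output paths) and mtime-based resume: a stage is
skipped when its outputs already exist and are newer than its inputs.

One master seed is fanned out per stage through ``numpy.random.SeedSequence``
so stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas_io, biomarker, longitudinal, morphometry, registration
from .atlas_io import LabeledAtlas, SubjectSeries
from .longitudinal import FeatureMatrix, MonthGrid, SubjectExclusionError
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort

log = logging.getLogger(__name__)

STAGES = ["synthesize", "validate", "featurize", "matrices", "select", "roc", "map"]


@dataclass
class RegistrationSettings:
    K: int = 6
    lam: float = 50.0
    levels: int = 3
    affine_max_iter: int = 30
    affine_tol: float = 1e-4
    nonrigid_max_iter: int = 8
    nonrigid_tol: float = 1e-4
    stride: int = 3


@dataclass
class SelectionSettings:
    n_folds: int = 6
    C: float = 1.0


@dataclass
class ROCSettings:
    n_test: int = 5
    n_reps: int = 1000
    bias_min: int = -50
    bias_max: int = 50
    kernel: str = "linear"
    C: float = 1.0


@dataclass
class PipelineConfig:
    """Every paper-silent constant surfaced in one validated config object."""

    cohort_dir: str = "cohort"
    out_dir: str = "out"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)
    grid: MonthGrid = field(default_factory=MonthGrid)
    selection: SelectionSettings = field(default_factory=SelectionSettings)
    roc: ROCSettings = field(default_factory=ROCSettings)

    def validate(self) -> None:
        self.cohort.validate()
        if self.registration.K < 1:
            raise ValueError("DCT basis order must be >= 1")
        if self.roc.bias_min >= self.roc.bias_max:
            raise ValueError("bias range must be increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            if dataclasses.is_dataclass(cur) and isinstance(val, dict):
                for k, v in val.items():
                    if not hasattr(cur, k):
                        raise ValueError(f"unknown config key {key}.{k}")
                    if k == "grid_shape" or k == "first_scan_window":
                        v = tuple(v)
                    setattr(cur, k, v)
            else:
                setattr(cfg, key, val)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence([self.seed, idx])
        return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# in-memory feature extraction


def featurize_scan(
    scan_vol: np.ndarray,
    atlas: LabeledAtlas,
    reg: RegistrationSettings = RegistrationSettings(),
    mask: np.ndarray | None = None,
    subject_id: str = "",
    scan_index: int = -1,
    day: int = -1,
    isolation: np.ndarray | None = None,
):
    """Register one scan to the template and extract its lobule features.

    Steps: isolation masking (zero everything outside the thresholded
    posterior-probability support), robust intensity normalization, 12-DOF
    affine registration, DCT-basis non-rigid registration, a
    single-interpolation warp into template space, then intensity and
    Jacobian lobule means.  The Jacobian is computed from the non-rigid
    displacement only; the affine component (global pose/size) is
    deliberately excluded.
    """
    if mask is None:
        mask = registration.default_mask(atlas.template)
    if isolation is not None:
        scan_vol = scan_vol * isolation
    norm = atlas_io.normalize_intensity(scan_vol, atlas.template)
    aff = registration.affine_register(
        norm, atlas.template, mask=mask, levels=reg.levels,
        max_iter=reg.affine_max_iter, tol=reg.affine_tol, stride=reg.stride,
    )
    deform, disp = registration.nonrigid_register(
        norm, atlas.template, init=aff, K=reg.K, lam=reg.lam, mask=mask,
        max_iter=reg.nonrigid_max_iter, tol=reg.nonrigid_tol,
        stride=reg.stride,
    )
    warped = registration.warp_scan(norm, aff, disp)
    intens, jac = morphometry.scan_features(
        warped, disp, atlas, subject_id, scan_index, day
    )
    return intens, jac, aff, deform, disp


def cohort_feature_matrices(
    series: list[SubjectSeries],
    atlas: LabeledAtlas,
    reg: RegistrationSettings = RegistrationSettings(),
    grid: MonthGrid = MonthGrid(),
    pmap: np.ndarray | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix, list[str]]:
    """Feature matrices (intensity, jacobian) for a registered cohort.

    ``pmap`` is the cerebellum/brain-stem posterior-probability map used for
    isolation (thresholded at p > 0.5); when absent, the template support
    stands in.  Returns the two matrices plus the ids of subjects excluded
    for having fewer than two scans inside the study window.  Row order is
    identical in both families.
    """
    mask = registration.default_mask(atlas.template)
    if pmap is not None:
        isolation = registration.threshold_probability(pmap)
    else:
        isolation = registration.default_mask(atlas.template, dilate=0)
    per_int: dict[str, np.ndarray] = {}
    per_jac: dict[str, np.ndarray] = {}
    outcomes: dict[str, int] = {}
    excluded: list[str] = []
    for s in series:
        means_int, means_jac = [], []
        for scan in s.scans:
            mi, mj, *_ = featurize_scan(
                scan.volume, atlas, reg, mask, s.subject_id, scan.scan_index,
                scan.day, isolation=isolation,
            )
            means_int.append(mi)
            means_jac.append(mj)
        try:
            bi = longitudinal.interpolate_subject(means_int, grid)
            bj = longitudinal.interpolate_subject(means_jac, grid)
        except SubjectExclusionError:
            excluded.append(s.subject_id)
            continue
        per_int[s.subject_id] = bi
        per_jac[s.subject_id] = bj
        outcomes[s.subject_id] = s.outcome
    fm_int = longitudinal.build_feature_matrix(
        per_int, outcomes, list(atlas.split_label_ids), morphometry.INTENSITY, grid
    )
    fm_jac = longitudinal.build_feature_matrix(
        per_jac, outcomes, list(atlas.split_label_ids), morphometry.JACOBIAN, grid
    )
    return fm_int, fm_jac, excluded


# ---------------------------------------------------------------------------
# cohort validation


def validate_cohort(cohort_dir: str | Path, horizon_days: int = 210) -> dict:
    """Consistency report for an on-disk cohort.

    Checks schedule/volume presence and loadability, grid agreement with the
    atlas, label integrity, and the >= 2 post-operative scans requirement;
    subjects failing the last check are listed as exclusions (with reasons),
    hard problems under ``errors``.
    """
    cohort_dir = Path(cohort_dir)
    report: dict = {"ok": False, "errors": [], "exclusions": [],
                    "n_subjects": 0, "n_scans": 0}
    if not cohort_dir.exists():
        report["errors"].append(f"missing cohort directory: {cohort_dir}")
        return report
    try:
        tpl, _ = atlas_io.load_volume(cohort_dir / "template.nii.gz")
        labels, _ = atlas_io.load_volume(cohort_dir / "labels.nii.gz")
    except Exception as exc:  # noqa: BLE001 - itemized report
        report["errors"].append(str(exc))
        return report
    if tpl.shape != labels.shape:
        report["errors"].append("template/labels grid mismatch")
    lab_int = np.asarray(labels)
    if not np.allclose(lab_int, np.round(lab_int)):
        report["errors"].append("label volume is not integer-valued")

    try:
        series = atlas_io.load_schedule(cohort_dir / "schedule.csv")
    except Exception as exc:  # noqa: BLE001
        report["errors"].append(str(exc))
        return report
    report["n_subjects"] = len(series)
    for s in series:
        n_window = sum(1 <= d <= horizon_days for d in s.days)
        if n_window < 2:
            report["exclusions"].append(
                {"subject": s.subject_id,
                 "reason": f"{n_window} scan(s) within [1, {horizon_days}]"}
            )
        for scan in s.scans:
            p = cohort_dir / "scans" / f"{s.subject_id}_scan{scan.scan_index:02d}.nii.gz"
            if not p.exists():
                report["errors"].append(f"missing scan volume: {p}")
                continue
            try:
                vol, _ = atlas_io.load_volume(p)
            except Exception as exc:  # noqa: BLE001
                report["errors"].append(f"{p}: {exc}")
                continue
            if vol.shape != tpl.shape:
                report["errors"].append(f"{p}: grid {vol.shape} != {tpl.shape}")
            report["n_scans"] += 1
    report["ok"] = not report["errors"]
    return report


# ---------------------------------------------------------------------------
# stages


def _outputs_fresh(outputs: list[Path], inputs: list[Path]) -> bool:
    if not outputs or not all(p.exists() for p in outputs):
        return False
    newest_in = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    return min(p.stat().st_mtime for p in outputs) >= newest_in


def _load_cohort(cfg: PipelineConfig):
    cohort_dir = Path(cfg.cohort_dir)
    atlas, _ = _load_cohort_atlas_only(cfg)
    series = atlas_io.load_schedule(cohort_dir / "schedule.csv")
    for s in series:
        for scan in s.scans:
            p = cohort_dir / "scans" / f"{s.subject_id}_scan{scan.scan_index:02d}.nii.gz"
            scan.volume, _ = atlas_io.load_volume(p)
    return atlas, series


def stage_synthesize(cfg: PipelineConfig, force: bool = False) -> dict:
    cohort_dir = Path(cfg.cohort_dir)
    outputs = [cohort_dir / "schedule.csv", cohort_dir / "template.nii.gz"]
    if not force and _outputs_fresh(outputs, []):
        log.info("synthesize: outputs present, skipping")
        return {"skipped": True}
    cohort_cfg = dataclasses.replace(cfg.cohort, seed=cfg.stage_seed("synthesize"))
    series, atlas, truth = generate_cohort(cohort_cfg)
    manifest = write_cohort(series, atlas, truth, cohort_dir, cohort_cfg)
    return {"skipped": False, "n_subjects": len(series),
            "paths": [manifest["schedule"], manifest["template"]]}


def stage_featurize(cfg: PipelineConfig, force: bool = False) -> dict:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_dir = Path(cfg.cohort_dir)
    out_csv = out_dir / "lobule_means.csv"
    inputs = [cohort_dir / "schedule.csv"]
    if not force and _outputs_fresh([out_csv], inputs):
        log.info("featurize: outputs fresh, skipping")
        return {"skipped": True}
    atlas, series = _load_cohort(cfg)
    mask = registration.default_mask(atlas.template)
    pmap_path = Path(cfg.cohort_dir) / "pmap.nii.gz"
    if pmap_path.exists():
        pmap, _ = atlas_io.load_volume(pmap_path)
        isolation = registration.threshold_probability(np.asarray(pmap))
    else:
        isolation = registration.default_mask(atlas.template, dilate=0)
    rows = []
    for s in series:
        for scan in s.scans:
            mi, mj, aff, deform, disp = featurize_scan(
                scan.volume, atlas, cfg.registration, mask,
                s.subject_id, scan.scan_index, scan.day, isolation=isolation,
            )
            for lm in (mi, mj):
                for lid, val in zip(lm.label_ids, lm.values):
                    rows.append(
                        (s.subject_id, scan.scan_index, scan.day, lm.family,
                         lid, val)
                    )
    df = pd.DataFrame(
        rows, columns=["subject", "scan", "day", "family", "label", "mean"]
    )
    df.to_csv(out_csv, index=False)
    return {"skipped": False, "n_rows": len(df), "paths": [str(out_csv)]}


def stage_matrices(cfg: PipelineConfig, force: bool = False) -> dict:
    out_dir = Path(cfg.out_dir)
    means_csv = out_dir / "lobule_means.csv"
    outputs = [out_dir / "features_intensity.csv", out_dir / "features_jacobian.csv"]
    if not force and _outputs_fresh(outputs, [means_csv]):
        log.info("matrices: outputs fresh, skipping")
        return {"skipped": True}
    df = pd.read_csv(means_csv)
    schedule = atlas_io.load_schedule(Path(cfg.cohort_dir) / "schedule.csv")
    outcomes = {s.subject_id: s.outcome for s in schedule}
    label_ids = sorted(int(v) for v in df["label"].unique())
    excluded = []
    for family, out_csv in zip(
        [morphometry.INTENSITY, morphometry.JACOBIAN], outputs
    ):
        sub = df[df["family"] == family]
        per_subject = {}
        for sid, g in sub.groupby("subject"):
            means = []
            for (scan, day), gg in g.groupby(["scan", "day"]):
                gg = gg.set_index("label").loc[label_ids]
                means.append(
                    morphometry.LobuleMeans(
                        label_ids=list(label_ids),
                        values=gg["mean"].to_numpy(),
                        family=family, subject_id=str(sid),
                        scan_index=int(scan), day=int(day),
                    )
                )
            try:
                per_subject[str(sid)] = longitudinal.interpolate_subject(
                    means, cfg.grid
                )
            except SubjectExclusionError:
                if str(sid) not in excluded:
                    excluded.append(str(sid))
        fm = longitudinal.build_feature_matrix(
            per_subject, outcomes, list(label_ids), family, cfg.grid
        )
        fm.to_csv(out_csv)
        fm.column_map_json(out_csv.with_suffix(".columns.json"))
    if excluded:
        (out_dir / "excluded_subjects.json").write_text(json.dumps(excluded))
    return {"skipped": False, "excluded": excluded,
            "paths": [str(p) for p in outputs]}


def _load_matrix(path: Path, family: str) -> FeatureMatrix:
    df = pd.read_csv(path)
    sids = df["subject"].astype(str).tolist()
    y = df["outcome"].to_numpy(dtype=int)
    cols = [c for c in df.columns if c not in ("subject", "outcome")]
    columns = [tuple(int(v) for v in c.rsplit("_", 1)) for c in cols]
    return FeatureMatrix(
        X=df[cols].to_numpy(dtype=float), y=y, subject_ids=sids,
        columns=columns, family=family,
    )


def _atlas_for_decode(cfg: PipelineConfig) -> LabeledAtlas:
    atlas, _ = _load_cohort_atlas_only(cfg)
    return atlas


def _load_cohort_atlas_only(cfg: PipelineConfig):
    cohort_dir = Path(cfg.cohort_dir)
    tpl, aff = atlas_io.load_volume(cohort_dir / "template.nii.gz")
    labels, _ = atlas_io.load_volume(cohort_dir / "labels.nii.gz")
    labels = np.asarray(labels).astype(np.int32)
    split_ids = sorted(int(v) for v in np.unique(labels) if v != 0)
    sym = sorted({l - atlas_io.LEFT_STRIDE if l > atlas_io.LEFT_STRIDE else l
                  for l in split_ids})
    atlas = LabeledAtlas(
        template=np.asarray(tpl, dtype=np.float64), labels=labels,
        voxel_to_world=aff, symmetric_label_ids=sym,
        split_label_ids=split_ids,
        split_map={},
    )
    atlas.split_map = {
        (atlas.symmetric_id_of(l), atlas.side_of(l)): l for l in split_ids
    }
    return atlas, None


def stage_select(cfg: PipelineConfig, force: bool = False) -> dict:
    out_dir = Path(cfg.out_dir)
    outputs = [out_dir / "selection_intensity.json",
               out_dir / "selection_jacobian.json"]
    inputs = [out_dir / "features_intensity.csv", out_dir / "features_jacobian.csv"]
    if not force and _outputs_fresh(outputs, inputs):
        log.info("select: outputs fresh, skipping")
        return {"skipped": True}
    atlas = _atlas_for_decode(cfg)
    seed = cfg.stage_seed("select")
    info = {}
    for family, fpath, opath in zip(
        [morphometry.INTENSITY, morphometry.JACOBIAN], inputs, outputs
    ):
        fm = _load_matrix(fpath, family)
        sel = biomarker.rfecv_select(
            fm, atlas, n_folds=cfg.selection.n_folds, C=cfg.selection.C,
            seed=seed,
        )
        sel.to_json(opath)
        pd.DataFrame(
            {"size": sel.sizes, "mean_cv_score": sel.cv_scores}
        ).to_csv(out_dir / f"rfecv_curve_{family}.csv", index=False)
        info[family] = {"optimal_size": sel.optimal_size,
                        "selected": sel.selected_columns}
    return {"skipped": False, "selection": info,
            "paths": [str(p) for p in outputs]}


def stage_roc(cfg: PipelineConfig, force: bool = False) -> dict:
    out_dir = Path(cfg.out_dir)
    outputs = [out_dir / "roc_intensity.json", out_dir / "roc_jacobian.json"]
    inputs = [out_dir / "selection_intensity.json",
              out_dir / "selection_jacobian.json"]
    if not force and _outputs_fresh(outputs, inputs):
        log.info("roc: outputs fresh, skipping")
        return {"skipped": True}
    seed = cfg.stage_seed("roc")
    info = {}
    for family, spath, opath in zip(
        [morphometry.INTENSITY, morphometry.JACOBIAN], inputs, outputs
    ):
        raw = json.loads(Path(spath).read_text())
        fm = _load_matrix(out_dir / f"features_{family}.csv", family)
        sel = biomarker.SelectionResult(
            family=family,
            sizes=np.asarray(raw["sizes"]),
            cv_scores=np.asarray(raw["cv_scores"]),
            optimal_size=raw["optimal_size"],
            selected_columns=raw["selected_columns"],
            decoded=raw["decoded"],
            mean_rank=np.asarray(raw["mean_rank"]),
        )
        results = biomarker.evaluate_feature_sets(
            sel, fm, n_test=cfg.roc.n_test, n_reps=cfg.roc.n_reps, seed=seed,
            C=cfg.roc.C, kernel=cfg.roc.kernel,
        )
        payload = [
            {"descriptor": r.descriptor, "auc": r.auc,
             "mean_tpr": r.mean_tpr.tolist(), "mean_fpr": r.mean_fpr.tolist()}
            for r in results
        ]
        Path(opath).write_text(json.dumps(payload, indent=2))
        info[family] = {r.descriptor: round(r.auc, 4) for r in results}
    return {"skipped": False, "auc": info, "paths": [str(p) for p in outputs]}


def stage_map(cfg: PipelineConfig, force: bool = False) -> dict:
    out_dir = Path(cfg.out_dir)
    atlas = _atlas_for_decode(cfg)
    paths = []
    for family in (morphometry.INTENSITY, morphometry.JACOBIAN):
        raw = json.loads((out_dir / f"selection_{family}.json").read_text())
        fm = _load_matrix(out_dir / f"features_{family}.csv", family)
        for entry in raw["decoded"]:
            bm = biomarker.map_biomarker(entry["column"], fm, atlas)
            p = out_dir / f"biomarker_{family}_{bm.side}{bm.symmetric_label}_m{bm.month}.png"
            biomarker.render_biomarker(bm, atlas, p)
            paths.append(str(p))
    return {"skipped": False, "paths": paths}


STAGE_FUNCS = {
    "synthesize": stage_synthesize,
    "featurize": stage_featurize,
    "matrices": stage_matrices,
    "select": stage_select,
    "roc": stage_roc,
    "map": stage_map,
}


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> dict:
    """Run all stages in order, skipping fresh ones; returns the manifest."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in STAGES},
        "stages": {},
    }
    for name in ["synthesize", "featurize", "matrices", "select", "roc", "map"]:
        t0 = time.perf_counter()
        try:
            result = STAGE_FUNCS[name](cfg, force=force)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        result["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][name] = result
        if name == "synthesize":
            report = validate_cohort(cfg.cohort_dir, cfg.grid.horizon_days)
            manifest["stages"]["validate"] = report
            if report.get("errors"):
                raise RuntimeError(f"cohort validation failed: {report['errors']}")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    return manifest
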