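"""End-to-end subject and cohort runs, file based or in memory.

Subject stage (the order is deliberate: smoothing precedes the nuisance
projection so regressed nuisance is never re-mixed across voxels):

    drop initial frames -> framewise displacement -> censor flags
    -> mask geometry (shell, contralateral homologue, cavity-excluded brain)
    -> mask-normalized smoothing -> simultaneous nuisance + bandpass projection
    -> seed-pair difference map and subject metric

Cohort stage: median-survival split with KS screen, Mann-Whitney U and
Cohen's d (full cohort and, when large enough, the Grade-IV subset), Spearman
correlation of the metric with 6-month KPS change, the multivariate OLS
outcome model, and leave-one-out SVM classification plus SVM / linear
regression.  Analyses whose subgroup is too small are skipped with the reason
recorded; the run continues.

Every run echoes its fully resolved configuration (all defaults made
explicit) plus a SHA-256 hash of that echo, so reports are self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, connectivity, lesion_masks, outcome_predict, preprocess
from .cohort_stats import SubjectRecord, kps_change
from .preprocess import NuisanceSet, PreprocConfig
from .volumes_io import (
    BinaryMask,
    MotionTrace,
    Volume4D,
    read_bold,
    read_mask,
    read_motion,
    write_volume,
)

__version__ = "0.1.0"


class PipelineError(Exception):
    """A stage failure, carrying the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str | None, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause
        where = f" (subject {subject_id})" if subject_id else ""
        super().__init__(f"stage {stage!r}{where} failed: {cause}")


@dataclass
class PipelineConfig:
    """All tunables of a run; defaults are the protocol's stated parameters."""

    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    dilation_iterations: int = 3
    dilation_connectivity: int = 6
    sphere_radius_mm: float = 5.0
    survival_cutoff_months: float = 15.0
    feature_set: str = "summary5"
    svm_c: float = 1.0
    svm_gamma: float | None = None
    rng_seed: int = 0

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["software_version"] = __version__
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class SubjectResult:
    subject_id: str
    diffmap: connectivity.DifferenceMap
    masks: lesion_masks.MaskSet
    qc: dict

    def summary(self) -> dict:
        return {"subject_id": self.subject_id, **self.diffmap.summary(), **self.qc}


def process_subject(
    bold: Volume4D,
    motion: MotionTrace,
    nuisance: NuisanceSet,
    resection: BinaryMask,
    brain: BinaryMask,
    config: PipelineConfig | None = None,
    subject_id: str = "subject",
) -> SubjectResult:
    """Run the full subject-level chain on in-memory inputs."""
    config = config or PipelineConfig()
    pp = config.preproc
    tr = bold.grid.tr_s
    if tr is None:
        raise PipelineError("validate", subject_id, ValueError("BOLD grid has no TR"))
    try:
        pp.validate(bold.n_frames, tr)
        bold.grid.require_same(resection.grid, "resection mask")
        bold.grid.require_same(brain.grid, "brain mask")
    except Exception as exc:
        raise PipelineError("validate", subject_id, exc) from exc

    try:
        series, motion_d = preprocess.drop_initial(bold, motion, pp.n_drop)
        nuis = nuisance.dropped(pp.n_drop) if nuisance.n_frames == bold.n_frames else nuisance
        if nuis.n_frames != series.n_frames:
            raise ValueError(
                f"nuisance frame count {nuis.n_frames} does not match "
                f"post-drop series length {series.n_frames}"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("drop_initial", subject_id, exc) from exc

    try:
        fd = preprocess.framewise_displacement(motion_d)
        cvec = preprocess.censor(fd, pp.censor_threshold_mm)
    except Exception as exc:
        raise PipelineError("censor", subject_id, exc) from exc

    try:
        masks = lesion_masks.build_mask_set(
            resection, brain, config.dilation_iterations, config.dilation_connectivity
        )
    except Exception as exc:
        raise PipelineError("masks", subject_id, exc) from exc

    try:
        smoothed = preprocess.smooth_gaussian(series, pp.fwhm_mm, masks.cavity_excluded_brain)
    except Exception as exc:
        raise PipelineError("smooth", subject_id, exc) from exc

    try:
        residual = preprocess.nuisance_bandpass_regress(smoothed, nuis, cvec, pp.band_hz)
    except Exception as exc:
        raise PipelineError("regress", subject_id, exc) from exc

    try:
        offsets = connectivity.sphere_offsets(config.sphere_radius_mm, bold.grid.voxel_mm)
        pairs = connectivity.make_seed_pairs(
            masks.perilesional, masks.brain, allowed=masks.cavity_excluded_brain
        )
        diffmap = connectivity.difference_map(
            residual, pairs, offsets, masks.cavity_excluded_brain
        )
    except Exception as exc:
        raise PipelineError("difference_map", subject_id, exc) from exc

    qc = {
        "n_frames_input": bold.n_frames,
        "n_frames_post_drop": series.n_frames,
        "n_censored": int(cvec.n_frames - cvec.n_retained),
        "n_retained": int(cvec.n_retained),
        "censored_frames": [int(f) for f in cvec.censored_frames],
        "tumor_volume_ml": lesion_masks.mask_volume_ml(resection),
        "contra_resection_overlap": masks.contra_resection_overlap,
    }
    return SubjectResult(subject_id=subject_id, diffmap=diffmap, masks=masks, qc=qc)


def write_subject_outputs(result: SubjectResult, outdir: str | os.PathLike) -> dict:
    """Write heatmap NIfTI, per-seed TSV, pairing TSV, and the subject JSON."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    sid = result.subject_id
    heat_path = os.path.join(outdir, f"{sid}_diffmap.nii.gz")
    write_volume(connectivity.heatmap_volume(result.diffmap), heat_path)
    seed_path = os.path.join(outdir, f"{sid}_seeds.tsv")
    result.diffmap.to_table().to_csv(seed_path, sep="\t", index=False)
    pair_path = os.path.join(outdir, f"{sid}_pairing.tsv")
    lesion_masks.pairing_table(result.masks.perilesional, result.masks.brain).to_csv(
        pair_path, sep="\t", index=False
    )
    json_path = os.path.join(outdir, f"{sid}_summary.json")
    with open(json_path, "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
    return {"heatmap": heat_path, "seeds": seed_path, "pairing": pair_path, "summary": json_path}


def _survival_label(record: SubjectRecord, cutoff: float) -> int:
    """1 = long survival (at or above the cutoff, or still alive), 0 = short."""
    return int(record.alive or record.survival_months >= cutoff)


def analyze_cohort(
    records: list[SubjectRecord],
    diffmaps: list[connectivity.DifferenceMap],
    config: PipelineConfig | None = None,
) -> dict:
    """Cohort statistics + LOOCV prediction from per-subject results.

    ``records[i].subject_metric`` is overwritten from ``diffmaps[i]``.
    Skipped analyses appear under ``"skipped"`` with their reason.
    """
    config = config or PipelineConfig()
    if len(records) != len(diffmaps):
        raise ValueError("records and diffmaps must be paired")
    if len(records) < 4:
        raise ValueError("cohort analysis needs at least 4 subjects")
    for rec, dm in zip(records, diffmaps):
        rec.subject_metric = dm.subject_metric

    report: dict = {"n_subjects": len(records), "skipped": {}}

    def _try(name: str, fn):
        try:
            report[name] = fn()
        except Exception as exc:
            report["skipped"][name] = f"{type(exc).__name__}: {exc}"

    _try("group_comparison", lambda: cohort_stats.compare_survival_groups(records).to_dict())

    grade4 = [r for r in records if r.who_grade == "IV"]
    if len(grade4) >= 4:
        _try(
            "group_comparison_grade_iv",
            lambda: cohort_stats.compare_survival_groups(grade4).to_dict(),
        )
    else:
        report["skipped"]["group_comparison_grade_iv"] = (
            f"only {len(grade4)} Grade IV subjects"
        )

    def _spearman_block(subset: list[SubjectRecord]) -> dict:
        xs, ys = [], []
        for r in subset:
            dk = kps_change(r)
            if dk is None:
                continue
            xs.append(r.subject_metric)
            ys.append(float(dk))
        rho, p = cohort_stats.spearman(xs, ys)
        return {"rho": rho, "p": p, "n": len(xs), "n_excluded": len(subset) - len(xs)}

    _try("spearman_metric_vs_kps", lambda: _spearman_block(records))
    _try("outcome_model", lambda: cohort_stats.fit_outcome_model(records).to_dict())
    if len(grade4) >= 4:
        _try("outcome_model_grade_iv", lambda: cohort_stats.fit_outcome_model(grade4).to_dict())

    X, feature_names = outcome_predict.build_features(diffmaps, config.feature_set)
    labels = [_survival_label(r, config.survival_cutoff_months) for r in records]
    report["features"] = {"names": list(feature_names), "n": len(records)}
    _try(
        "loocv_classification",
        lambda: outcome_predict.loocv_classify(X, labels, config.svm_c, config.svm_gamma).to_dict(),
    )

    kps_rows = [(i, kps_change(r)) for i, r in enumerate(records)]
    kps_idx = [i for i, dk in kps_rows if dk is not None]
    kps_y = [float(dict(kps_rows)[i]) for i in kps_idx]
    report["kps_n_included"] = len(kps_idx)
    for model in ("svm_rbf", "linear"):
        _try(
            f"loocv_regression_{model}",
            lambda m=model: outcome_predict.loocv_regress(
                X[kps_idx], kps_y, m, config.svm_c, config.svm_gamma
            ).to_dict(),
        )

    report["config"] = config.resolved()
    report["config_hash"] = config.config_hash()
    return report


def run_cohort_subjects(
    subjects: list,
    config: PipelineConfig | None = None,
) -> tuple[list[SubjectResult], dict]:
    """Process a list of in-memory subjects (e.g. synthetic) and analyze the cohort."""
    config = config or PipelineConfig()
    results = []
    for s in subjects:
        results.append(
            process_subject(
                s.bold, s.motion, s.nuisance, s.resection, s.brain, config, s.subject_id
            )
        )
    records = [s.record for s in subjects]
    report = analyze_cohort(records, [r.diffmap for r in results], config)
    report["subjects"] = [r.summary() for r in results]
    return results, report


# ---------------------------------------------------------------------------
# file-based entry points


def _config_from_dict(d: dict) -> PipelineConfig:
    pp = d.get("preproc", {})
    band = pp.get("band_hz", (0.005, 0.1))
    return PipelineConfig(
        preproc=PreprocConfig(
            n_drop=pp.get("n_drop", 5),
            band_hz=(float(band[0]), float(band[1])),
            fwhm_mm=pp.get("fwhm_mm", 6.0),
            censor_threshold_mm=pp.get("censor_threshold_mm", 0.3),
            censor_use_rotations=pp.get("censor_use_rotations", False),
        ),
        dilation_iterations=d.get("dilation_iterations", 3),
        dilation_connectivity=d.get("dilation_connectivity", 6),
        sphere_radius_mm=d.get("sphere_radius_mm", 5.0),
        survival_cutoff_months=d.get("survival_cutoff_months", 15.0),
        feature_set=d.get("feature_set", "summary5"),
        svm_c=d.get("svm_c", 1.0),
        svm_gamma=d.get("svm_gamma"),
        rng_seed=d.get("rng_seed", 0),
    )


def load_run_config(path: str | os.PathLike) -> tuple[dict, PipelineConfig]:
    """Load and validate a YAML run config; returns (raw dict, PipelineConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "subjects" not in raw:
        raise ValueError(f"{path}: run config must be a mapping with a 'subjects' section")
    for sid, entry in raw["subjects"].items():
        for key in ("bold", "resection_mask", "brain_mask", "motion"):
            if key not in entry:
                raise ValueError(f"subject {sid}: missing config field {key!r}")
            if not os.path.exists(entry[key]):
                raise FileNotFoundError(f"subject {sid}: {key} path {entry[key]} not found")
    return raw, _config_from_dict(raw.get("options", {}))


def _load_subject_inputs(entry: dict):
    bold = read_bold(entry["bold"])
    resection = read_mask(entry["resection_mask"], bold.grid)
    brain = read_mask(entry["brain_mask"], bold.grid)
    motion = read_motion(entry["motion"])
    if "nuisance" in entry:
        arr = np.loadtxt(entry["nuisance"], comments="#", ndmin=2)
        if arr.shape[1] < 2:
            raise ValueError(f"nuisance file {entry['nuisance']} needs 2 columns")
        nuis = NuisanceSet(
            motion=motion.params, ventricle_signal=arr[:, 0], white_matter_signal=arr[:, 1]
        )
    else:
        raise ValueError("subject entry needs a 'nuisance' TSV (ventricle, white matter)")
    return bold, motion, nuis, resection, brain


def _record_from_entry(sid: str, entry: dict, tumor_volume_ml: float) -> SubjectRecord:
    c = entry.get("clinical", {})
    return SubjectRecord(
        id=sid,
        age_years=float(c["age_years"]),
        sex=str(c["sex"]),
        who_grade=str(c["who_grade"]),
        tumor_volume_ml=tumor_volume_ml,
        survival_months=float(c["survival_months"]),
        alive=bool(c["alive"]),
        kps_pre=int(c["kps_pre"]),
        kps_6mo=None if c.get("kps_6mo") in (None, "") else int(c["kps_6mo"]),
    )


def run_subject(config_path: str | os.PathLike, subject_id: str, outdir: str | os.PathLike) -> dict:
    """File-based subject run: read inputs, process, write outputs."""
    raw, config = load_run_config(config_path)
    if subject_id not in raw["subjects"]:
        raise ValueError(f"subject {subject_id!r} not in config")
    entry = raw["subjects"][subject_id]
    bold, motion, nuis, resection, brain = _load_subject_inputs(entry)
    result = process_subject(bold, motion, nuis, resection, brain, config, subject_id)
    return write_subject_outputs(result, outdir)


def run_cohort(config_path: str | os.PathLike, outdir: str | os.PathLike) -> dict:
    """File-based cohort run: all subjects, then the full cohort report."""
    raw, config = load_run_config(config_path)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    results, records = [], []
    for sid, entry in raw["subjects"].items():
        bold, motion, nuis, resection, brain = _load_subject_inputs(entry)
        result = process_subject(bold, motion, nuis, resection, brain, config, sid)
        write_subject_outputs(result, os.path.join(outdir, sid))
        results.append(result)
        records.append(_record_from_entry(sid, entry, result.qc["tumor_volume_ml"]))
    report = analyze_cohort(records, [r.diffmap for r in results], config)
    report["subjects"] = [r.summary() for r in results]
    report_path = os.path.join(outdir, "cohort_report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    pd.DataFrame([r.summary() for r in results]).to_csv(
        os.path.join(outdir, "subject_metrics.tsv"), sep="\t", index=False
    )
    return report
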