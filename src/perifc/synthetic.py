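"""Synthetic postsurgical fMRI subjects and cohorts.

The generator emulates the statistical structure the analysis assumes, at a
desk scale every test can afford: a left-right symmetric ellipsoidal brain on
a 24 x 24 x 16 grid of 3.75 x 3.75 x 4 mm voxels (TR 2.4 s, 120 frames before
dropping), a spherical resection cavity of exact zeros on one hemisphere, and
a BOLD model in which every brain voxel loads on one shared band-limited
(0.01-0.08 Hz) latent network series g(t):

    y(v, t) = beta(v) g(t) + w_v vent(t) + w_w wm(t) + noise(v, t)

with coupling ``beta_c`` on the mirrored contralateral shell, a *deficit*
``delta`` reducing the perilesional shell to ``beta_c - delta``, a weak
background coupling elsewhere in brain, and exact zeros inside the cavity.
Ventricle and white-matter confounds are added globally with known weights so
the nuisance regression has something real to remove, and the motion trace is
near-zero jitter with level shifts producing framewise displacement above the
0.3 mm censor threshold at chosen frames.

Clinical outcomes are generated from the planted physiology: short-survival
subjects carry large deficits and lognormal survival under 15 months,
long-survival subjects small deficits and survival at or above 15 months
(some flagged alive), and the 6-month KPS change is linear in the expected
connectivity metric plus noise, quantized to the 10-point KPS scale.  These
links are generative conveniences that make the group separation and the
metric-KPS correlation recoverable; nothing in the analysis pipeline knows
about them.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import lesion_masks
from .connectivity import sphere_offsets
from .cohort_stats import SubjectRecord
from .preprocess import NuisanceSet
from .volumes_io import (
    BinaryMask,
    MotionTrace,
    Volume4D,
    VoxelGrid,
    write_motion,
    write_volume,
)


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class SimParams:
    """All knobs of the subject simulator, with desk-scale defaults."""

    dims: tuple[int, int, int] = (24, 24, 16)
    voxel_mm: tuple[float, float, float] = (3.75, 3.75, 4.0)
    tr_s: float = 2.4
    n_frames: int = 120                     # pre-drop
    n_drop: int = 5
    brain_semiaxes_vox: tuple[float, float, float] = (10.8, 10.8, 7.2)
    cavity_center: tuple[int, int, int] = (5, 12, 8)
    cavity_radius_vox: float = 2.0
    beta_c: float = 0.75                    # contralateral-shell coupling
    delta: float = 0.0                      # perilesional coupling deficit
    beta_bg_frac: float = 0.25              # background coupling as fraction of beta_c
    noise_sd: float = 1.0
    network_band_hz: tuple[float, float] = (0.01, 0.08)
    nuisance_weight_ventricle: float = 0.4
    nuisance_weight_white_matter: float = 0.4
    motion_spike_frames: tuple[int, ...] = (37, 81)   # post-drop frame indices
    motion_spike_mm: float = 0.5
    motion_jitter_sd_mm: float = 0.02
    dilation_iterations: int = 3
    sphere_radius_mm: float = 5.0
    kps_slope: float = 150.0
    kps_intercept: float = 5.0
    kps_noise_sd: float = 4.0
    kps_link_gamma: float = 0.5
    survival_group: str | None = None       # "short" | "long" | None

    def __post_init__(self) -> None:
        if not (0 <= self.delta <= self.beta_c):
            raise SimulationError(f"need 0 <= delta <= beta_c, got delta={self.delta}")
        if self.noise_sd <= 0 or self.kps_noise_sd <= 0:
            raise SimulationError("noise SDs must be positive")
        if self.n_drop >= self.n_frames:
            raise SimulationError("n_drop must be below n_frames")
        for f in self.motion_spike_frames:
            if not (1 <= f < self.n_frames - self.n_drop):
                raise SimulationError(f"spike frame {f} outside post-drop range")

    @property
    def beta_p(self) -> float:
        return self.beta_c - self.delta

    @property
    def beta_bg(self) -> float:
        return self.beta_c * self.beta_bg_frac

    def grid(self) -> VoxelGrid:
        return VoxelGrid(dims=self.dims, voxel_mm=self.voxel_mm, tr_s=self.tr_s)


@dataclass
class SyntheticSubject:
    subject_id: str
    bold: Volume4D
    resection: BinaryMask
    brain: BinaryMask
    motion: MotionTrace
    nuisance: NuisanceSet
    record: SubjectRecord
    truth: dict


def make_brain(params: SimParams) -> BinaryMask:
    """Left-right symmetric ellipsoidal brain mask."""
    grid = params.grid()
    centers = [(d - 1) / 2.0 for d in params.dims]
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in params.dims), indexing="ij")
    a, b, c = params.brain_semiaxes_vox
    dist = (
        ((ii - centers[0]) / a) ** 2
        + ((jj - centers[1]) / b) ** 2
        + ((kk - centers[2]) / c) ** 2
    )
    return BinaryMask(grid, dist <= 1.0)


def make_cavity(params: SimParams, brain: BinaryMask) -> BinaryMask:
    """Spherical (in voxel units) resection cavity, strictly inside the brain."""
    grid = params.grid()
    cx, cy, cz = params.cavity_center
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in params.dims), indexing="ij")
    sphere = (ii - cx) ** 2 + (jj - cy) ** 2 + (kk - cz) ** 2 <= params.cavity_radius_vox ** 2
    if not sphere.any():
        raise SimulationError("cavity is empty")
    edge = (
        sphere[0].any() or sphere[-1].any()
        or sphere[:, 0].any() or sphere[:, -1].any()
        or sphere[:, :, 0].any() or sphere[:, :, -1].any()
    )
    if edge:
        raise SimulationError("cavity touches the grid boundary")
    if (sphere & ~brain.data).any():
        raise SimulationError("cavity is not strictly inside the brain mask")
    return BinaryMask(grid, sphere)


def _bandlimited_series(
    rng: np.random.Generator,
    n_frames: int,
    tr_s: float,
    band_hz: tuple[float, float],
) -> np.ndarray:
    """Unit-SD series with power only at DFT frequencies inside ``band_hz``."""
    t = np.arange(n_frames)
    total_s = n_frames * tr_s
    low, high = band_hz
    ks = [k for k in range(1, n_frames // 2 + 1) if low <= k / total_s <= high]
    if not ks:
        raise SimulationError(f"no DFT frequency inside band {band_hz}")
    g = np.zeros(n_frames)
    for k in ks:
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.rayleigh(1.0)
        g += amp * np.cos(2 * np.pi * k * t / n_frames + phase)
    g -= g.mean()
    return g / g.std()


def expected_metric(params: SimParams) -> float:
    """Closed-form monotone link from the planted deficit to the metric.

    Treats the target as background-coupled voxels and the seed as a
    ``k``-voxel sphere average (``k`` from the sphere spec), ignoring smoothing
    and shell-target contributions; used to generate outcomes and to predict
    the metric's sign, not as an unbiased estimate of the recovered value.
    """
    k = len(sphere_offsets(params.sphere_radius_mm, params.voxel_mm))
    s2 = params.noise_sd ** 2

    def r(beta_seed: float, beta_target: float) -> float:
        denom = np.sqrt((beta_seed ** 2 + s2 / k) * (beta_target ** 2 + s2))
        return beta_seed * beta_target / denom

    return float(
        np.arctanh(r(params.beta_p, params.beta_bg))
        - np.arctanh(r(params.beta_c, params.beta_bg))
    )


def _round10(x: float) -> int:
    return int(np.round(x / 10.0) * 10)


def _make_record(
    subject_id: str,
    params: SimParams,
    tumor_volume_ml: float,
    rng: np.random.Generator,
) -> SubjectRecord:
    age = float(np.clip(np.round(rng.normal(47.0, 12.0), 1), 25.0, 75.0))
    sex = "male" if rng.random() < 1.0 / 3.0 else "female"
    who_grade = rng.choice(["I", "II", "IV"], p=[1 / 12, 2 / 12, 9 / 12])
    group = params.survival_group
    if group == "short":
        survival = float(np.clip(rng.lognormal(np.log(5.0), 0.6), 1.0, 13.5))
        alive = False
    elif group == "long":
        survival = float(np.clip(15.0 + rng.lognormal(np.log(25.0), 0.7), 15.0, 70.0))
        alive = bool(rng.random() < 2.0 / 3.0)
    else:
        survival = 24.0
        alive = False
    m = expected_metric(params)
    # strictly monotone link from the planted metric to the KPS-change scale; the
    # sub-linear exponent keeps small-deficit subjects spread across more than one
    # 10-point KPS step instead of collapsing onto a single tied level
    link = np.sign(m) * abs(m) ** params.kps_link_gamma
    change_target = params.kps_intercept + params.kps_slope * link + rng.normal(0, params.kps_noise_sd)
    if (not alive) and survival < 6.0:
        # death before follow-up: KPS change is 0 - kps_pre by definition, so
        # place kps_pre so the change still follows the planted link
        kps_pre = int(np.clip(_round10(-change_target), 10, 100))
        kps_6mo = None
    else:
        kps_pre = int(rng.choice([70, 80, 90]))
        kps_6mo = int(np.clip(kps_pre + _round10(change_target), 0, 100))
    return SubjectRecord(
        id=subject_id,
        age_years=age,
        sex=sex,
        who_grade=str(who_grade),
        tumor_volume_ml=tumor_volume_ml,
        survival_months=survival,
        alive=alive,
        kps_pre=kps_pre,
        kps_6mo=kps_6mo,
    )


def make_subject(
    params: SimParams,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sub-01",
) -> SyntheticSubject:
    """Generate one subject: BOLD, masks, motion, nuisance, clinical record, truth."""
    rng = np.random.default_rng(seed)
    grid = params.grid()
    brain = make_brain(params)
    resection = make_cavity(params, brain)
    shell = lesion_masks.perilesional_shell(
        resection, brain, iterations=params.dilation_iterations
    )
    contra = lesion_masks.mirror(shell, brain)

    n = params.n_frames
    g = _bandlimited_series(rng, n, params.tr_s, params.network_band_hz)
    vent = _bandlimited_series(rng, n, params.tr_s, (0.005, 0.04))
    wm = _bandlimited_series(rng, n, params.tr_s, (0.005, 0.04))

    beta = np.zeros(params.dims)
    beta[brain.data] = params.beta_bg
    beta[contra.data] = params.beta_c
    beta[shell.data] = params.beta_p
    beta[resection.data] = 0.0

    confound = params.nuisance_weight_ventricle * vent + params.nuisance_weight_white_matter * wm
    series = beta[..., None] * g[None, None, None, :]
    series = series + brain.data[..., None] * confound[None, None, None, :]
    noise = rng.normal(0.0, params.noise_sd, size=params.dims + (n,))
    series = series + brain.data[..., None] * noise
    series[resection.data] = 0.0
    series[~brain.data] = 0.0
    bold = Volume4D(grid, series)

    # motion: tiny jitter plus level shifts at the requested (post-drop) frames
    trans = rng.normal(0.0, params.motion_jitter_sd_mm, size=(n, 3))
    rot = rng.normal(0.0, 0.005, size=(n, 3))
    for i, f in enumerate(params.motion_spike_frames):
        trans[f + params.n_drop :, i % 3] += params.motion_spike_mm
    motion = MotionTrace(np.hstack([trans, rot]))

    nuisance = NuisanceSet(motion=motion.params, ventricle_signal=vent, white_matter_signal=wm)
    tumor_ml = lesion_masks.mask_volume_ml(resection)
    record = _make_record(subject_id, params, tumor_ml, rng)
    truth = {
        "delta": params.delta,
        "beta_c": params.beta_c,
        "beta_p": params.beta_p,
        "expected_metric": expected_metric(params),
        "expected_sign": -1 if params.delta > 0 else 0,
        "survival_group": params.survival_group,
    }

    assert not bold.series[resection.data].any(), "cavity voxels must be exactly zero"
    assert np.array_equal(brain.data, np.flip(brain.data, axis=grid.left_right_axis)), \
        "brain mask must be left-right symmetric"

    return SyntheticSubject(
        subject_id=subject_id,
        bold=bold,
        resection=resection,
        brain=brain,
        motion=motion,
        nuisance=nuisance,
        record=record,
        truth=truth,
    )


def make_symmetric_subject(
    params: SimParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sub-sym",
) -> SyntheticSubject:
    """An exactly left-right symmetric null subject.

    The resection is the union of the cavity and its mirror image and the BOLD
    series is symmetrized voxelwise, so every mask and every time series the
    pipeline touches is mirror-symmetric and the subject metric must vanish up
    to floating-point error.  This is a null construction for testing the
    difference map's symmetry, not a physiologically plausible subject.
    """
    params = params or SimParams(delta=0.0)
    s = make_subject(params, seed=seed, subject_id=subject_id)
    axis = s.bold.grid.left_right_axis
    res_sym = BinaryMask(
        s.resection.grid, s.resection.data | np.flip(s.resection.data, axis=axis)
    )
    series = 0.5 * (s.bold.series + np.flip(s.bold.series, axis=axis))
    series[res_sym.data] = 0.0
    s.bold = Volume4D(s.bold.grid, series)
    s.resection = res_sym
    s.record.tumor_volume_ml = lesion_masks.mask_volume_ml(res_sym)
    s.truth = {**s.truth, "symmetric_null": True, "expected_metric": 0.0, "expected_sign": 0}
    return s


def default_cohort_params(base: SimParams | None = None) -> tuple[SimParams, SimParams]:
    """Short- and long-survival subject templates; the per-subject deficit is
    drawn in :func:`make_cohort` from the group's deficit-fraction range."""
    base = base or SimParams()
    return replace(base, survival_group="short"), replace(base, survival_group="long")


def make_cohort(
    n: int = 12,
    params_short: SimParams | None = None,
    params_long: SimParams | None = None,
    seed: int = 0,
    delta_frac_short: tuple[float, float] = (0.5, 0.9),
    delta_frac_long: tuple[float, float] = (0.0, 0.25),
    vary_cavity: bool = False,
) -> list[SyntheticSubject]:
    """A balanced cohort: n/2 large-deficit short-survival subjects and n/2
    small-deficit long-survival subjects, deterministically seeded.

    By default every subject shares the template's cavity geometry, so the
    planted deficit is the only physiological difference between subjects
    (tumor volume is then constant and the outcome model drops it).  With
    ``vary_cavity`` the resection radius and centre jitter across subjects so
    tumor volume becomes a real covariate; the cavity stays lateral (never
    touches the midline), so contralateral homologues remain lesion-free, but
    the varying shell geometry adds metric variance that is not carried by the
    planted outcome link.
    """
    if n % 2 != 0 or n < 4:
        raise SimulationError("the balanced default design needs an even n >= 4")
    if params_short is None or params_long is None:
        ps, pl = default_cohort_params()
        params_short = params_short or ps
        params_long = params_long or pl
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    draw_rng = np.random.default_rng(children[0])
    subjects = []
    for i in range(n):
        if i < n // 2:
            lo, hi = delta_frac_short
            template = params_short
        else:
            lo, hi = delta_frac_long
            template = params_long
        frac = float(draw_rng.uniform(lo, hi))
        params = replace(template, delta=frac * template.beta_c)
        if vary_cavity:
            cx, cy, cz = template.cavity_center
            params = replace(
                params,
                cavity_radius_vox=float(draw_rng.uniform(1.6, 2.5)),
                cavity_center=(
                    cx,
                    cy + int(draw_rng.integers(-1, 2)),
                    cz + int(draw_rng.integers(-1, 2)),
                ),
            )
        subjects.append(
            make_subject(params, seed=children[i + 1], subject_id=f"sub-{i + 1:02d}")
        )
    return subjects


def write_subject(subject: SyntheticSubject, outdir: str | os.PathLike) -> dict:
    """Write one subject's files (NIfTI + TSV) and return their paths."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "bold": os.path.join(outdir, f"{subject.subject_id}_bold.nii.gz"),
        "resection_mask": os.path.join(outdir, f"{subject.subject_id}_resection.nii.gz"),
        "brain_mask": os.path.join(outdir, f"{subject.subject_id}_brain.nii.gz"),
        "motion": os.path.join(outdir, f"{subject.subject_id}_motion.tsv"),
        "nuisance": os.path.join(outdir, f"{subject.subject_id}_nuisance.tsv"),
    }
    write_volume(subject.bold, paths["bold"])
    write_volume(subject.resection.to_volume3d(), paths["resection_mask"])
    write_volume(subject.brain.to_volume3d(), paths["brain_mask"])
    write_motion(subject.motion, paths["motion"])
    np.savetxt(
        paths["nuisance"],
        np.column_stack([subject.nuisance.ventricle_signal, subject.nuisance.white_matter_signal]),
        delimiter="\t",
        fmt="%.10g",
        header="ventricle\twhite_matter",
    )
    return paths


def write_cohort(subjects: list[SyntheticSubject], outdir: str | os.PathLike) -> str:
    """Write a cohort directory: per-subject files, records TSV, truth JSON.

    Returns the path of a run-config YAML fragment-compatible manifest (JSON).
    """
    import pandas as pd

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    manifest = {"subjects": {}}
    rows = []
    truth = {}
    for s in subjects:
        paths = write_subject(s, os.path.join(outdir, s.subject_id))
        rec = s.record
        manifest["subjects"][s.subject_id] = {
            **paths,
            "clinical": {
                "age_years": rec.age_years,
                "sex": rec.sex,
                "who_grade": rec.who_grade,
                "survival_months": rec.survival_months,
                "alive": rec.alive,
                "kps_pre": rec.kps_pre,
                "kps_6mo": rec.kps_6mo,
            },
        }
        rows.append(
            {
                "id": rec.id,
                "age_years": rec.age_years,
                "sex": rec.sex,
                "who_grade": rec.who_grade,
                "tumor_volume_ml": rec.tumor_volume_ml,
                "survival_months": rec.survival_months,
                "alive": int(rec.alive),
                "kps_pre": rec.kps_pre,
                "kps_6mo": "" if rec.kps_6mo is None else rec.kps_6mo,
            }
        )
        truth[s.subject_id] = s.truth
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "records.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path
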