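"""Temporal and spatial denoising of a BOLD series.

The cleaning chain is: drop the initial non-steady-state frames, flag
high-motion frames (framewise displacement above a threshold), smooth each
frame with an anisotropy-corrected Gaussian restricted to a brain mask, then
remove nuisance structure and out-of-band frequency content in one
least-squares projection evaluated on the retained frames only.

Filtering and nuisance removal are deliberately a *single* simultaneous
regression rather than sequential filtering followed by censoring: censoring
after a temporal filter reintroduces the censored artifact into neighbouring
frames, whereas a joint projection is well defined on the irregular time grid
that censoring leaves behind.  The design contains an intercept, a linear
trend, the six motion parameters, the ventricle and white-matter signals, and
sine/cosine pairs at every DFT frequency outside the pass band.  The global
(whole-brain mean) signal is never included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes_io import BinaryMask, MotionTrace, Volume4D

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PreprocError(Exception):
    """Base class for preprocessing failures."""


class TooFewFramesError(PreprocError):
    """Not enough frames remain for the requested operation."""


class CollinearDesignError(PreprocError):
    """The nuisance design matrix is rank deficient."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"collinear design columns: {', '.join(columns)}")


@dataclass
class CensorVector:
    """Per-frame retention flags (True = retained) at a displacement threshold."""

    flags: np.ndarray
    threshold_mm: float = 0.3

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.flags.size

    @property
    def n_retained(self) -> int:
        return int(self.flags.sum())

    @property
    def censored_frames(self) -> np.ndarray:
        return np.flatnonzero(~self.flags)


@dataclass
class NuisanceSet:
    """Nuisance series sharing the post-drop frame count.

    The whole-brain global signal must never be added here; removing it is
    known to induce spurious anti-correlations.
    """

    motion: np.ndarray            # (T, 6)
    ventricle_signal: np.ndarray  # (T,)
    white_matter_signal: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=np.float64)
        self.ventricle_signal = np.asarray(self.ventricle_signal, dtype=np.float64).ravel()
        self.white_matter_signal = np.asarray(self.white_matter_signal, dtype=np.float64).ravel()
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError(f"motion must be (T, 6), got {self.motion.shape}")
        t = self.motion.shape[0]
        if self.ventricle_signal.size != t or self.white_matter_signal.size != t:
            raise ValueError("nuisance series lengths disagree with motion trace")

    @property
    def n_frames(self) -> int:
        return self.motion.shape[0]

    def dropped(self, n_drop: int) -> "NuisanceSet":
        return NuisanceSet(
            motion=self.motion[n_drop:],
            ventricle_signal=self.ventricle_signal[n_drop:],
            white_matter_signal=self.white_matter_signal[n_drop:],
        )


@dataclass
class PreprocConfig:
    n_drop: int = 5
    band_hz: tuple[float, float] = (0.005, 0.1)
    fwhm_mm: float = 6.0
    censor_threshold_mm: float = 0.3
    censor_use_rotations: bool = False  # displacement from translations only by default

    def validate(self, n_frames: int, tr_s: float) -> None:
        if not (0 <= self.n_drop < n_frames):
            raise ValueError(f"n_drop={self.n_drop} out of range for {n_frames} frames")
        low, high = self.band_hz
        nyquist = 1.0 / (2.0 * tr_s)
        if not (0 < low < high < nyquist):
            raise ValueError(f"band {self.band_hz} must satisfy 0 < low < high < {nyquist}")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")


def drop_initial(series: Volume4D, motion: MotionTrace, n_drop: int) -> tuple[Volume4D, MotionTrace]:
    """Remove the first ``n_drop`` frames from the series and trace consistently."""
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if n_drop >= series.n_frames:
        raise TooFewFramesError(
            f"cannot drop {n_drop} of {series.n_frames} frames"
        )
    if motion.n_frames != series.n_frames:
        raise ValueError(
            f"motion trace has {motion.n_frames} frames, series has {series.n_frames}"
        )
    return (
        Volume4D(series.grid, series.series[..., n_drop:]),
        MotionTrace(motion.params[n_drop:]),
    )


def framewise_displacement(motion: MotionTrace) -> np.ndarray:
    """Per-frame head displacement (mm).

    Frame 0 is 0 by convention; frame t is the Euclidean norm of the
    frame-to-frame difference of the three translation parameters.  Rotations
    are ignored: no rotation-to-displacement radius convention is assumed.
    """
    if motion.n_frames < 1:
        raise ValueError("motion trace is empty")
    fd = np.zeros(motion.n_frames)
    if motion.n_frames > 1:
        diffs = np.diff(motion.translations_mm, axis=0)
        fd[1:] = np.linalg.norm(diffs, axis=1)
    return fd


def censor(displacement: np.ndarray, threshold_mm: float = 0.3) -> CensorVector:
    """Flag frames with displacement strictly above ``threshold_mm`` for removal."""
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    displacement = np.asarray(displacement, dtype=np.float64)
    flags = displacement <= threshold_mm
    if flags.sum() < 2:
        raise TooFewFramesError(
            f"only {int(flags.sum())} frames retained at threshold {threshold_mm} mm; "
            "correlation is undefined"
        )
    return CensorVector(flags=flags, threshold_mm=threshold_mm)


def smooth_gaussian(series: Volume4D, fwhm_mm: float, brain: BinaryMask) -> Volume4D:
    """Mask-normalized Gaussian smoothing of every frame.

    Sigma per axis is ``fwhm / (2 sqrt(2 ln 2)) / voxel_mm_axis``, correcting for
    anisotropic voxels.  Weights are renormalized over the mask so values from
    outside it (cavity, non-brain) never smear in; voxels outside the mask are
    zeroed.  ``fwhm_mm = 0`` is the identity inside the mask.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    series.grid.require_same(brain.grid, "smoothing mask")
    m = brain.data.astype(np.float64)
    if fwhm_mm == 0:
        out = series.series * m[..., None]
        return Volume4D(series.grid, out)
    sigma_vox = tuple(
        fwhm_mm * FWHM_TO_SIGMA / d for d in series.grid.voxel_mm
    )
    sm_mask = ndimage.gaussian_filter(m, sigma=sigma_vox, mode="constant", cval=0.0)
    data = series.series * m[..., None]
    sm = ndimage.gaussian_filter(
        data, sigma=sigma_vox + (0.0,), mode="constant", cval=0.0
    )
    out = np.zeros_like(series.series)
    inside = brain.data & (sm_mask > 1e-12)
    out[inside] = sm[inside] / sm_mask[inside][:, None]
    return Volume4D(series.grid, out)


def build_design(
    n_frames: int,
    tr_s: float,
    nuisance: NuisanceSet,
    band_hz: tuple[float, float] = (0.005, 0.1),
) -> tuple[np.ndarray, list[str]]:
    """Design matrix spanning everything to be removed from the data.

    Columns: intercept, linear trend, 6 motion parameters, ventricle signal,
    white-matter signal, and a sine/cosine pair at every DFT frequency
    ``k / (n_frames * tr_s)`` outside ``[low, high]`` (cosine only at the
    Nyquist bin for even ``n_frames``).  Non-intercept columns are demeaned.
    """
    if nuisance.n_frames != n_frames:
        raise ValueError(
            f"nuisance has {nuisance.n_frames} frames, series has {n_frames}"
        )
    low, high = band_hz
    t = np.arange(n_frames, dtype=np.float64)
    cols: list[np.ndarray] = [np.ones(n_frames)]
    names: list[str] = ["intercept"]

    trend = t - t.mean()
    if np.ptp(trend) > 0:
        trend = trend / np.abs(trend).max()
    cols.append(trend)
    names.append("trend")

    for j in range(6):
        cols.append(nuisance.motion[:, j] - nuisance.motion[:, j].mean())
        names.append(f"motion{j}")
    cols.append(nuisance.ventricle_signal - nuisance.ventricle_signal.mean())
    names.append("ventricle")
    cols.append(nuisance.white_matter_signal - nuisance.white_matter_signal.mean())
    names.append("white_matter")

    total_s = n_frames * tr_s
    eps = 1e-12
    for k in range(1, n_frames // 2 + 1):
        f = k / total_s
        if low - eps <= f <= high + eps:
            continue
        phase = 2.0 * np.pi * f * t * tr_s
        cols.append(np.cos(phase))
        names.append(f"cos_k{k}")
        if not (n_frames % 2 == 0 and k == n_frames // 2):
            cols.append(np.sin(phase))
            names.append(f"sin_k{k}")
    return np.column_stack(cols), names


def nuisance_bandpass_regress(
    series: Volume4D,
    nuisance: NuisanceSet,
    censor_vec: CensorVector,
    band_hz: tuple[float, float] = (0.005, 0.1),
    design: tuple[np.ndarray, list[str]] | None = None,
) -> Volume4D:
    """Project out nuisance and out-of-band structure; return retained-frame residuals.

    A single least-squares projection per voxel onto the orthogonal complement
    of the design span, fit on retained frames only.  Censored frames are
    deleted (not interpolated) and stay excluded from every downstream
    correlation.  The returned series has ``censor_vec.n_retained`` frames.
    """
    n = series.n_frames
    if censor_vec.n_frames != n:
        raise ValueError(
            f"censor vector covers {censor_vec.n_frames} frames, series has {n}"
        )
    if series.grid.tr_s is None:
        raise ValueError("series grid carries no TR; cannot build frequency columns")
    if design is None:
        design = build_design(n, series.grid.tr_s, nuisance, band_hz)
    X, names = design
    keep = censor_vec.flags
    Xr = X[keep]
    n_ret = Xr.shape[0]
    if n_ret < 2:
        raise TooFewFramesError("fewer than 2 retained frames")
    if n_ret <= Xr.shape[1]:
        raise TooFewFramesError(
            f"{n_ret} retained frames do not exceed {Xr.shape[1]} regressors"
        )
    # rank check with named collinear columns
    norms = np.linalg.norm(Xr, axis=0)
    norms[norms == 0] = 1.0
    svals = np.linalg.svd(Xr / norms, compute_uv=False)
    if svals[-1] < 1e-10 * svals[0]:
        _, r = np.linalg.qr(Xr / norms)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise CollinearDesignError(bad or names)

    Y = series.series.reshape(-1, n).T[keep]  # (n_ret, n_vox)
    beta, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
    resid = Y - Xr @ beta
    out = resid.T.reshape(series.grid.dims + (n_ret,))
    grid = series.grid
    return Volume4D(grid, out)
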