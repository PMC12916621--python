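"""Seed-based whole-brain connectivity and the perilesional difference map.

For every voxel of the perilesional shell, a spherical ROI (default radius
5 mm, clipped to the allowed mask) is averaged into a seed time series, the
Pearson correlation of that series with every voxel of the cavity-excluded
brain is Fisher z-transformed, and the mean z over the brain is that seed's
whole-brain connectivity.  The same is done for the seed's mirrored
contralateral counterpart, and the per-voxel difference

    entry(v) = mean_z_wholebrain(peri seed v) - mean_z_wholebrain(contra seed v)

forms the difference map.  The subject-level scalar metric is the arithmetic
mean of the entries: negative values mean the perilesional shell is less
coupled to the rest of the brain than its mirror image.

Both the perilesional and the contralateral seeds are correlated against one
common target mask (the cavity-excluded brain), which makes the subtraction
well-posed.  Zero-variance target voxels contribute z = 0 (and are tallied)
rather than being dropped, so both sides average over identical voxel sets.
Seeds whose mirrored voxel falls outside the brain are excluded from the map
and counted as unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .lesion_masks import mirror_index
from .volumes_io import BinaryMask, Volume3D, Volume4D, VoxelGrid

Z_CLIP = 1.0 - 1e-7


class ConnectivityError(Exception):
    """Base class for connectivity failures."""


class ConstantSeedError(ConnectivityError):
    """A seed time series has zero variance; correlation is undefined."""


class EmptySphereError(ConnectivityError):
    """No sphere voxel of a seed lies inside the allowed mask."""


class NoPairedSeedsError(ConnectivityError):
    """Every perilesional seed lost its contralateral counterpart."""


@dataclass(frozen=True)
class SeedPair:
    """A perilesional seed voxel and its mirrored contralateral counterpart."""

    peri_index: tuple[int, int, int]
    contra_index: tuple[int, int, int]
    paired: bool


@dataclass(frozen=True)
class SphereSpec:
    radius_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


class SeedZ(NamedTuple):
    """Mean whole-brain Fisher z of one seed plus the zero-variance tally."""

    value: float
    n_zero_variance: int


@dataclass
class DifferenceMap:
    """Per-perilesional-voxel connectivity differences plus the subject scalar."""

    grid: VoxelGrid
    entries: dict[tuple[int, int, int], float]
    z_peri: dict[tuple[int, int, int], float]
    z_contra: dict[tuple[int, int, int], float]
    subject_metric: float
    n_pairs: int
    n_unpaired: int
    n_zero_variance_targets: int

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "peri_x": k[0], "peri_y": k[1], "peri_z": k[2],
                "z_peri": self.z_peri[k],
                "z_contra": self.z_contra[k],
                "difference": self.entries[k],
            }
            for k in self.entries
        ]
        return pd.DataFrame(
            rows, columns=["peri_x", "peri_y", "peri_z", "z_peri", "z_contra", "difference"]
        )

    def summary(self) -> dict:
        return {
            "subject_metric": self.subject_metric,
            "n_pairs": self.n_pairs,
            "n_unpaired": self.n_unpaired,
            "n_zero_variance_targets": self.n_zero_variance_targets,
        }


def sphere_offsets(radius_mm: float, voxel_mm: tuple[float, float, float]) -> list[tuple[int, int, int]]:
    """Integer voxel offsets within ``radius_mm`` of the origin in physical units."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    dx, dy, dz = voxel_mm
    ri, rj, rk = (int(np.floor(radius_mm / d)) for d in (dx, dy, dz))
    out = []
    for i in range(-ri, ri + 1):
        for j in range(-rj, rj + 1):
            for k in range(-rk, rk + 1):
                if (i * dx) ** 2 + (j * dy) ** 2 + (k * dz) ** 2 <= radius_mm ** 2:
                    out.append((i, j, k))
    return out


def seed_series(
    series: Volume4D,
    seed: tuple[int, int, int],
    offsets: list[tuple[int, int, int]],
    allowed: BinaryMask,
) -> np.ndarray:
    """Unweighted mean BOLD series over the seed's sphere ∩ allowed mask."""
    dims = series.grid.dims
    coords = np.asarray(seed, dtype=int) + np.asarray(offsets, dtype=int)
    inb = np.all((coords >= 0) & (coords < np.asarray(dims)), axis=1)
    coords = coords[inb]
    keep = allowed.data[coords[:, 0], coords[:, 1], coords[:, 2]]
    coords = coords[keep]
    if coords.shape[0] == 0:
        raise EmptySphereError(f"no sphere voxel of seed {tuple(seed)} inside allowed mask")
    return series.series[coords[:, 0], coords[:, 1], coords[:, 2], :].mean(axis=0)


def fisher_z(r: float) -> float:
    """atanh(r) with |r| clipped just below 1 so perfect correlations stay finite."""
    if abs(r) > 1 + 1e-12:
        raise ValueError(f"|r| > 1: {r}")
    return float(np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP)))


class _TargetCorrelator:
    """Caches the z-scored target-voxel series so each seed costs one matvec."""

    def __init__(self, series: Volume4D, target: BinaryMask):
        series.grid.require_same(target.grid, "correlation target")
        if series.n_frames < 3:
            raise ConnectivityError("need at least 3 retained frames for correlation")
        idx = target.indices()
        if idx.shape[0] == 0:
            raise ConnectivityError("target mask is empty")
        X = series.series[idx[:, 0], idx[:, 1], idx[:, 2], :]  # (V, T)
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        self.zero_var = norms == 0
        safe = np.where(self.zero_var, 1.0, norms)
        self.Xn = Xc / safe[:, None]
        self.n_zero_variance = int(self.zero_var.sum())

    def mean_z(self, seed_ts: np.ndarray) -> SeedZ:
        sc = seed_ts - seed_ts.mean()
        nrm = np.linalg.norm(sc)
        if nrm == 0:
            raise ConstantSeedError("seed time series is constant")
        r = self.Xn @ (sc / nrm)
        z = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
        z[self.zero_var] = 0.0
        return SeedZ(float(z.mean()), self.n_zero_variance)


def seed_wholebrain_z(series: Volume4D, seed_ts: np.ndarray, target: BinaryMask) -> SeedZ:
    """Mean Fisher z between one seed series and every target voxel's series."""
    return _TargetCorrelator(series, target).mean_z(np.asarray(seed_ts, dtype=np.float64))


def make_seed_pairs(peri: BinaryMask, brain: BinaryMask, allowed: BinaryMask | None = None) -> list[SeedPair]:
    """Pair every perilesional voxel with its mirror; flag pairs leaving brain.

    A pair is valid when the mirrored voxel lies in the brain mask and (if an
    ``allowed`` mask is given, normally the cavity-excluded brain) also in the
    allowed mask, so the contralateral seed series is well defined.
    """
    peri.grid.require_same(brain.grid, "seed pairing")
    pairs = []
    for idx in peri.indices():
        p = tuple(int(v) for v in idx)
        c = mirror_index(p, peri.grid)
        ok = bool(brain.data[c])
        if ok and allowed is not None:
            ok = bool(allowed.data[c])
        pairs.append(SeedPair(peri_index=p, contra_index=c, paired=ok))
    return pairs


def difference_map(
    series: Volume4D,
    pairs: list[SeedPair],
    offsets: list[tuple[int, int, int]],
    target: BinaryMask,
) -> DifferenceMap:
    """Perilesional-minus-contralateral whole-brain connectivity per seed pair.

    ``target`` is both the correlation target and the allowed mask for sphere
    averaging (the cavity-excluded brain).  By linearity, the mean over targets
    of the voxelwise z difference equals the difference of the two mean-z
    values; the latter is what is computed.
    """
    corr = _TargetCorrelator(series, target)
    entries: dict = {}
    z_peri: dict = {}
    z_contra: dict = {}
    n_unpaired = 0
    for pair in pairs:
        if not pair.paired:
            n_unpaired += 1
            continue
        ts_p = seed_series(series, pair.peri_index, offsets, target)
        ts_c = seed_series(series, pair.contra_index, offsets, target)
        zp = corr.mean_z(ts_p)
        zc = corr.mean_z(ts_c)
        z_peri[pair.peri_index] = zp.value
        z_contra[pair.peri_index] = zc.value
        entries[pair.peri_index] = zp.value - zc.value
    if not entries:
        raise NoPairedSeedsError("zero paired seeds; no difference map can be formed")
    metric = float(np.mean(list(entries.values())))
    return DifferenceMap(
        grid=series.grid,
        entries=entries,
        z_peri=z_peri,
        z_contra=z_contra,
        subject_metric=metric,
        n_pairs=len(entries),
        n_unpaired=n_unpaired,
        n_zero_variance_targets=corr.n_zero_variance,
    )


def heatmap_volume(diffmap: DifferenceMap) -> Volume3D:
    """The difference map as a volume: entry values at perilesional voxels, 0 elsewhere."""
    vals = np.zeros(diffmap.grid.dims)
    for (i, j, k), v in diffmap.entries.items():
        vals[i, j, k] = v
    return Volume3D(diffmap.grid, vals)
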