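"""Perilesional shell, contralateral homologue and cavity-excluded brain masks.

Starting from a binary resection-cavity mask and a whole-brain mask on the same
grid, this module derives:

* the **perilesional shell** — the resection mask dilated by a fixed number of
  face-neighbour (6-connected) iterations, minus the resection itself,
  intersected with brain.  Three iterations at an in-plane resolution of
  3.75 mm approximate the ~1 cm margin typically preserved around eloquent
  tissue during resection.
* the **contralateral homologue** — the shell reflected across the mid-grid
  plane of the left-right axis (``x -> nx - 1 - x``) and intersected with
  brain, so non-brain voxels never enter the reference region.
* the **cavity-excluded brain** — brain minus resection, the target over which
  every seed's whole-brain connectivity is computed, so the zero-valued
  surgical cavity never contributes.

Dilation is plain grid dilation clipped to the array bounds, with the brain
intersection applied afterwards (not geodesically during dilation); 18- and
26-connected structuring elements are available as options.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes_io import BinaryMask, VoxelGrid


class MaskError(Exception):
    """Base class for mask-construction failures."""


class EmptyMaskError(MaskError):
    """An operation produced (or requires) a nonempty mask."""


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class MaskSet:
    """All masks a subject's connectivity analysis needs, on one grid.

    ``contra_resection_overlap`` counts contralateral voxels falling inside the
    resection mask; for valid subjects (lesion away from the midline) it is 0,
    mirroring the visual tumor-free check done on real contralateral regions.
    """

    resection: BinaryMask
    perilesional: BinaryMask
    contralateral: BinaryMask
    brain: BinaryMask
    cavity_excluded_brain: BinaryMask
    contra_resection_overlap: int = 0

    def check_invariants(self) -> None:
        assert not (self.perilesional.data & self.resection.data).any(), \
            "perilesional shell intersects resection"
        assert not (self.perilesional.data & ~self.brain.data).any(), \
            "perilesional shell leaves brain"
        assert not (self.contralateral.data & ~self.brain.data).any(), \
            "contralateral mask leaves brain"
        assert np.array_equal(
            self.cavity_excluded_brain.data, self.brain.data & ~self.resection.data
        ), "cavity_excluded_brain != brain \\ resection"


def dilate(mask: BinaryMask, iterations: int, connectivity: int = 6) -> BinaryMask:
    """``iterations`` successive binary dilations, clipped to the grid bounds."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    if iterations == 0:
        return BinaryMask(mask.grid, mask.data.copy())
    out = ndimage.binary_dilation(
        mask.data, structure=_STRUCTS[connectivity], iterations=iterations
    )
    return BinaryMask(mask.grid, out)


def perilesional_shell(
    resection: BinaryMask,
    brain: BinaryMask,
    iterations: int = 3,
    connectivity: int = 6,
) -> BinaryMask:
    """(dilate(resection) \\ resection) ∩ brain."""
    resection.grid.require_same(brain.grid, "perilesional shell")
    if not brain.data.any():
        raise EmptyMaskError("brain mask is empty")
    grown = dilate(resection, iterations, connectivity)
    shell = grown.data & ~resection.data & brain.data
    if not shell.any():
        raise EmptyMaskError("perilesional shell is empty (no perilesional tissue)")
    return BinaryMask(resection.grid, shell)


def mirror(mask: BinaryMask, brain: BinaryMask) -> BinaryMask:
    """Reflect across the mid-grid plane of the left-right axis, then ∩ brain."""
    mask.grid.require_same(brain.grid, "mirroring")
    axis = mask.grid.left_right_axis
    flipped = np.flip(mask.data, axis=axis)
    return BinaryMask(mask.grid, flipped & brain.data)


def mirror_index(idx, grid: VoxelGrid) -> tuple[int, int, int]:
    """Mirror a single voxel index across the mid-grid plane."""
    out = [int(v) for v in idx]
    ax = grid.left_right_axis
    out[ax] = grid.dims[ax] - 1 - out[ax]
    return tuple(out)


def cavity_excluded(brain: BinaryMask, resection: BinaryMask) -> BinaryMask:
    """brain \\ resection; fails if nothing remains."""
    brain.grid.require_same(resection.grid, "cavity exclusion")
    out = brain.data & ~resection.data
    if not out.any():
        raise EmptyMaskError("cavity-excluded brain is empty")
    return BinaryMask(brain.grid, out)


def mask_volume_ml(mask: BinaryMask) -> float:
    """Mask volume in millilitres (voxel count x voxel volume / 1000)."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0


def build_mask_set(
    resection: BinaryMask,
    brain: BinaryMask,
    iterations: int = 3,
    connectivity: int = 6,
) -> MaskSet:
    """Derive the full MaskSet from resection + brain and check its invariants."""
    shell = perilesional_shell(resection, brain, iterations, connectivity)
    contra = mirror(shell, brain)
    overlap = int((contra.data & resection.data).sum())
    mset = MaskSet(
        resection=resection,
        perilesional=shell,
        contralateral=contra,
        brain=brain,
        cavity_excluded_brain=cavity_excluded(brain, resection),
        contra_resection_overlap=overlap,
    )
    mset.check_invariants()
    return mset


def pairing_table(peri: BinaryMask, brain: BinaryMask) -> pd.DataFrame:
    """Per perilesional voxel: its mirrored index and whether the pair is in brain."""
    rows = []
    for idx in peri.indices():
        contra = mirror_index(idx, peri.grid)
        rows.append(
            {
                "peri_x": int(idx[0]),
                "peri_y": int(idx[1]),
                "peri_z": int(idx[2]),
                "contra_x": contra[0],
                "contra_y": contra[1],
                "contra_z": contra[2],
                "paired_flag": int(bool(brain.data[contra])),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peri_x", "peri_y", "peri_z",
            "contra_x", "contra_y", "contra_z", "paired_flag",
        ],
    )
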