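"""Potential maps on tissue interfaces.

A surface is the set of voxels of one tissue that touch (6-connectivity) a
partner tissue: the scalp surface is (scalp, external air), the outer dura
surface (dura, hard skull), the inner dura surface (dura, CSF), the
cortical surface (gray, CSF), and so on.  Potentials are sampled at the
named tissue's voxel centers.  Maps can be restricted to the upper part of
the head (the phantom analogue of "above eye level") and common-average
referenced; referencing after capping matches the convention that only the
retained points enter the comparison sums.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ValidationError
from .phantom import Tissue, VoxelModel
from .solver import PotentialVolume

__all__ = ["SurfaceMap", "extract_interface", "apply_average_reference", "cap_above_plane"]

_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass
class SurfaceMap:
    """Sampled potentials on one tissue interface."""

    voxels: np.ndarray  # (N, 3) int
    positions_mm: np.ndarray  # (N, 3)
    potentials: np.ndarray  # (N,) V
    name: str
    referenced: bool = False

    def __len__(self) -> int:
        return self.voxels.shape[0]

    @property
    def std(self) -> float:
        """Population standard deviation of the map's potentials (V)."""
        return float(self.potentials.std())


def interface_mask(model: VoxelModel, tissue: Tissue, neighbor: Tissue) -> np.ndarray:
    """Boolean grid of ``tissue`` voxels with a 6-neighbor of ``neighbor``."""
    lab = model.labels
    own = lab == int(tissue)
    nb = lab == int(neighbor)
    touch = np.zeros_like(own)
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        touch[tuple(sl_lo)] |= nb[tuple(sl_hi)]
        touch[tuple(sl_hi)] |= nb[tuple(sl_lo)]
    return own & touch


def extract_interface(
    model: VoxelModel,
    potential: PotentialVolume,
    tissue: Tissue,
    neighbor: Tissue,
    name: str | None = None,
) -> SurfaceMap:
    """Extract the (tissue, neighbor) interface with its potentials.

    Raises
    ------
    ValidationError
        If the interface is empty (including tissue == neighbor).
    """
    if tissue == neighbor:
        raise ValidationError(
            f"empty interface: a tissue ({tissue.name}) has no interface with itself"
        )
    mask = interface_mask(model, tissue, neighbor)
    voxels = np.argwhere(mask)
    if voxels.shape[0] == 0:
        raise ValidationError(
            f"empty interface between {tissue.name} and {neighbor.name}"
        )
    pots = potential.phi[tuple(voxels.T)]
    if np.any(~np.isfinite(pots)):
        raise ValidationError(
            f"interface {tissue.name}/{neighbor.name} touches voxels without "
            "solved potentials"
        )
    return SurfaceMap(
        voxels=voxels,
        positions_mm=model.positions_mm(voxels),
        potentials=pots,
        name=name or f"{tissue.name.lower()}|{neighbor.name.lower()}",
    )


def apply_average_reference(surface: SurfaceMap) -> SurfaceMap:
    """Common-average reference: shift potentials to zero mean (idempotent)."""
    if len(surface) == 0:
        raise ValidationError("cannot reference an empty surface map")
    return replace(
        surface,
        potentials=surface.potentials - surface.potentials.mean(),
        referenced=True,
    )


def cap_above_plane(surface: SurfaceMap, z_cut_mm: float) -> SurfaceMap:
    """Restrict a map to points with z >= z_cut (mm).

    Re-referencing is not applied automatically; callers choose the order
    (the experiments cap first, then reference over the retained points).

    Raises
    ------
    ValidationError
        If no point survives the cut.
    """
    keep = surface.positions_mm[:, 2] >= z_cut_mm
    if not keep.any():
        raise ValidationError(f"no surface points above z = {z_cut_mm} mm")
    return SurfaceMap(
        voxels=surface.voxels[keep],
        positions_mm=surface.positions_mm[keep],
        potentials=surface.potentials[keep],
        name=surface.name,
        referenced=surface.referenced,
    )
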