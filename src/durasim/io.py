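"""Readers, writers, run manifests and figure generation.

Label, conductivity and potential volumes travel as NIfTI (integer labels,
mm voxel sizes in the affine); tables and surface maps as CSV; reports and
manifests as JSON.  Voxel indexing is 0-based with axis order (x, y, z)
matching the NIfTI affine, and all mm coordinates are voxel centers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .phantom import ConductivityTable, Tissue, VoxelModel
from .surfaces import SurfaceMap

__all__ = [
    "logger",
    "RunManifest",
    "read_label_volume",
    "write_label_volume",
    "write_scalar_volume",
    "write_surface_csv",
    "read_surface_csv",
    "write_conductivity_csv",
    "read_conductivity_csv",
    "write_potentials_csv",
    "write_distribution_csv",
    "write_json_report",
    "render_contour_map",
]

logger = logging.getLogger("durasim")


def _affine(voxel_size: float, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    aff[:3, 3] = origin
    return aff


def write_label_volume(model: VoxelModel, path: str | os.PathLike) -> None:
    """Write a tissue-label volume as integer NIfTI."""
    img = nib.Nifti1Image(
        model.labels.astype(np.int16), _affine(model.voxel_size, model.origin)
    )
    nib.save(img, os.fspath(path))


def read_label_volume(
    path: str | os.PathLike,
    label_map: Mapping[int, Tissue] | None = None,
) -> VoxelModel:
    """Read a segmentation volume into a :class:`VoxelModel`.

    Parameters
    ----------
    label_map
        Mapping of integer codes in the file to tissues.  If omitted, the
        file's integers must already be valid :class:`Tissue` codes.  Two
        integers may map to the same tissue (labels are merged).

    Raises
    ------
    ValidationError
        For non-integer data or integer codes without a mapping.

    Warns if voxels are anisotropic by more than 10% (the largest pitch is
    used).
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValidationError(f"label volume {path} has non-integer voxel values")
        data = np.round(data).astype(np.int32)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if zooms.max() > 1.1 * zooms.min():
        warnings.warn(
            f"anisotropic voxels {tuple(zooms)} exceed 10%; treating as "
            f"isotropic with pitch {zooms.max():g} mm",
            RuntimeWarning,
            stacklevel=2,
        )
    voxel_size = float(zooms.max())

    present = np.unique(data)
    if label_map is not None:
        unmapped = [int(v) for v in present if int(v) not in label_map]
        if unmapped:
            raise ValidationError(f"no tissue mapping for integer labels: {unmapped}")
        lut = np.zeros(int(present.max()) + 1, dtype=np.int16)
        for code, tissue in label_map.items():
            if code <= present.max():
                lut[code] = int(tissue)
        labels = lut[data]
    else:
        valid = {int(t) for t in Tissue}
        unknown = [int(v) for v in present if int(v) not in valid]
        if unknown:
            raise ValidationError(
                f"unknown integer labels without a mapping: {unknown}"
            )
        labels = data.astype(np.int16)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return VoxelModel(labels=labels, voxel_size=voxel_size, origin=origin)


def write_scalar_volume(
    values: np.ndarray,
    voxel_size: float,
    origin: np.ndarray,
    path: str | os.PathLike,
) -> None:
    """Write a float volume (potential, conductivity, flux magnitude)."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(voxel_size, origin))
    nib.save(img, os.fspath(path))


def write_surface_csv(surface: SurfaceMap, path: str | os.PathLike) -> None:
    """Surface map as CSV: i,j,k,x_mm,y_mm,z_mm,potential_V,surface_name."""
    df = pd.DataFrame(
        {
            "i": surface.voxels[:, 0],
            "j": surface.voxels[:, 1],
            "k": surface.voxels[:, 2],
            "x_mm": surface.positions_mm[:, 0],
            "y_mm": surface.positions_mm[:, 1],
            "z_mm": surface.positions_mm[:, 2],
            "potential_V": surface.potentials,
            "surface_name": surface.name,
        }
    )
    df.to_csv(path, index=False)


def read_surface_csv(path: str | os.PathLike) -> SurfaceMap:
    df = pd.read_csv(path)
    return SurfaceMap(
        voxels=df[["i", "j", "k"]].to_numpy(dtype=int),
        positions_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        potentials=df["potential_V"].to_numpy(dtype=float),
        name=str(df["surface_name"].iloc[0]) if len(df) else "surface",
    )


def write_potentials_csv(
    points_m: np.ndarray, potentials_v: np.ndarray, path: str | os.PathLike
) -> None:
    """Analytic-oracle output: point coordinates (m) and potentials (V)."""
    pts = np.asarray(points_m, dtype=float)
    pd.DataFrame(
        {
            "x_m": pts[:, 0],
            "y_m": pts[:, 1],
            "z_m": pts[:, 2],
            "potential_V": np.asarray(potentials_v, dtype=float),
        }
    ).to_csv(path, index=False)


def write_distribution_csv(summary, path: str | os.PathLike) -> None:
    """Histogram + empirical CDF of a :class:`DistributionSummary` as CSV."""
    hist = pd.DataFrame(
        {
            "bin_left": summary.bin_edges[:-1],
            "bin_right": summary.bin_edges[1:],
            "count": summary.counts,
        }
    )
    cdf = pd.DataFrame(
        {
            "value": summary.sorted_values,
            "cumulative_fraction": summary.cumulative_fractions,
        }
    )
    hist["kind"] = "histogram"
    cdf["kind"] = "cdf"
    pd.concat([hist, cdf], ignore_index=True).to_csv(path, index=False)


def write_conductivity_csv(table: ConductivityTable, path: str | os.PathLike) -> None:
    """Conductivity table as CSV mirroring the literature layout."""
    rows = []
    for tissue, e in sorted(table.entries.items(), key=lambda kv: kv[0].name):
        rows.append(
            {
                "tissue": tissue.name.lower(),
                "mean_resistivity_ohm_cm": e.mean_resistivity_ohm_cm,
                "lower_resistivity_ohm_cm": e.lower_resistivity_ohm_cm,
                "upper_resistivity_ohm_cm": e.upper_resistivity_ohm_cm,
                "mean_conductivity_s_cm": e.mean_conductivity_s_cm,
                "conductivity_s_m": e.conductivity_s_m,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_conductivity_csv(path: str | os.PathLike) -> ConductivityTable:
    from .phantom import conductivity_from_table

    df = pd.read_csv(path)
    rows = {}
    for _, r in df.iterrows():
        tissue = Tissue[str(r["tissue"]).upper()]
        rows[tissue] = (
            float(r["mean_resistivity_ohm_cm"]),
            float(r["lower_resistivity_ohm_cm"]),
            float(r["upper_resistivity_ohm_cm"]),
        )
    return conductivity_from_table(rows)


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, Tissue):
            return o.name.lower()
        return super().default(o)


def write_json_report(report: Mapping | object, path: str | os.PathLike) -> None:
    """Serialize a report (dict or object with ``to_dict``) as JSON."""
    data = report.to_dict() if hasattr(report, "to_dict") else report
    p = Path(path)
    tmp = p.with_suffix(p.suffix + ".tmp")
    tmp.write_text(json.dumps(data, indent=2, cls=_JSONEncoder))
    tmp.replace(p)


@dataclass
class RunManifest:
    """Provenance record sufficient to reproduce a run."""

    stage: str
    config: dict
    seeds: list[int]
    outputs: list[str] = field(default_factory=list)
    inputs: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""
    config_hash: str = ""

    def finalize(self) -> "RunManifest":
        from . import __version__

        self.version = __version__
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        blob = json.dumps(self.config, sort_keys=True, cls=_JSONEncoder)
        self.config_hash = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return self

    def write(self, path: str | os.PathLike) -> None:
        """Write the manifest atomically (write-then-rename)."""
        self.finalize()
        write_json_report(self.__dict__, path)


def render_contour_map(
    surface: SurfaceMap,
    path: str | os.PathLike | None = None,
    ax: plt.Axes | None = None,
    vlim: tuple[float, float] | None = None,
    title: str | None = None,
    units: str = "V",
) -> tuple[float, float]:
    """Top-view contour plot of an upper-surface potential map.

    The map is projected onto the (x, y) plane viewed from above with
    anterior (+y) up and subject-left on plot-left.  ``vlim`` fixes the
    color limits so several panels can share one scale; the limits used
    are returned.

    Raises
    ------
    ValidationError
        If the map is empty.
    """
    if len(surface) == 0:
        raise ValidationError("cannot render an empty surface map")
    x = surface.positions_mm[:, 0]
    y = surface.positions_mm[:, 1]
    v = surface.potentials
    if vlim is None:
        vmax = float(np.max(np.abs(v)))
        vmax = vmax if vmax > 0 else 1.0
        vlim = (-vmax, vmax)

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(5, 5))
    if np.ptp(v) == 0:
        # degenerate constant map: flat color panel
        ax.tricontourf(x, y, np.zeros_like(v) + v, levels=1, vmin=vlim[0], vmax=vlim[1])
    else:
        levels = np.linspace(vlim[0], vlim[1], 21)
        ax.tricontourf(x, y, v, levels=levels, cmap="RdBu_r", extend="both")
    ax.set_aspect("equal")
    ax.set_xlabel("left - right (mm)")
    ax.set_ylabel("posterior - anterior (mm)")
    if title:
        ax.set_title(title)
    if own_fig:
        sm = plt.cm.ScalarMappable(
            cmap="RdBu_r", norm=plt.Normalize(vmin=vlim[0], vmax=vlim[1])
        )
        fig.colorbar(sm, ax=ax, label=f"potential ({units})")
        if path is not None:
            fig.savefig(os.fspath(path), dpi=120, bbox_inches="tight")
        plt.close(fig)
    return vlim
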