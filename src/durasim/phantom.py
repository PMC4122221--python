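"""Synthetic head phantoms, tissue conductivities and distributed dipole sources.

The study geometry is a nested-shell head: white matter at the core, a
cortical gray-matter ribbon whose inner (white/gray) interface can be
corrugated to emulate gyri and sulci, then CSF, a thin dura layer, hard and
soft skull bone, scalp, and external air.  Tissue conductivities follow the
standard literature compilation used in EEG forward modeling, ingested as
resistivities in Ohm*cm and converted to SI (S/m) for computation.

The cortical source model places one current dipole in every gray-matter
voxel, oriented along the local white->gray surface normal, with magnitudes
drawn i.i.d. uniform on a configurable range (default 0 to 0.4 mA*m per
voxel, i.e. one dipole per ~1 mm^3 hypercolumn patch).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, GeometryError, ValidationError

__all__ = [
    "Tissue",
    "TissueConductivity",
    "ConductivityTable",
    "VoxelModel",
    "ConductivityVolume",
    "Corrugation",
    "SourceConfig",
    "CorticalNormals",
    "DipoleField",
    "TABLE1_RESISTIVITIES",
    "conductivity_from_table",
    "builtin_conductivity_table",
    "build_shell_phantom",
    "default_head_radii",
    "realize_conductivity",
    "replace_tissue",
    "compute_cortical_normals",
    "sample_dipole_field",
]


class Tissue(enum.IntEnum):
    """Integer tissue labels used in voxelized head models."""

    AIR_EXTERNAL = 0
    AIR_INTERNAL = 1
    SCALP = 2
    FAT = 3
    MUSCLE = 4
    SKULL_HARD = 5
    SKULL_SOFT = 6
    DURA = 7
    CSF = 8
    GRAY = 9
    WHITE = 10
    BLOOD = 11
    EYE = 12
    CEREBELLUM = 13
    BASAL_GANGLIA = 14
    CORPUS_CALLOSUM = 15
    SALIVARY_GLANDS = 16
    SOFT_TISSUE = 17
    THALAMUS = 18


#: Mean resistivity with (lower, upper) bounds, in Ohm*cm, for each tissue,
#: plus the conventionally printed conductivity in S/cm.  Bounds are +-50%
#: of the mean except where the literature spread is wider.  The printed
#: external-air conductivity (1e-6 S/cm) is inconsistent with its own
#: resistivity (1/1e5 = 1e-5 S/cm); external air is treated as a perfect
#: insulator by the solver, so only the resistivity is used here.
TABLE1_RESISTIVITIES: dict[Tissue, tuple[float, float, float, float]] = {
    Tissue.AIR_INTERNAL: (50_000.0, 50_000.0, 100_000.0, 2e-5),
    Tissue.AIR_EXTERNAL: (100_000.0, 100_000.0, 100_000.0, 1e-6),
    Tissue.BASAL_GANGLIA: (700.0, 350.0, 1_050.0, 1.42e-3),
    Tissue.BLOOD: (160.0, 80.0, 240.0, 6.25e-3),
    Tissue.WHITE: (700.0, 350.0, 1_050.0, 1.42e-3),
    Tissue.GRAY: (300.0, 150.0, 450.0, 3.334e-3),
    Tissue.CEREBELLUM: (650.0, 325.0, 975.0, 1.54e-3),
    Tissue.CSF: (65.0, 32.5, 97.5, 1.54e-2),
    Tissue.CORPUS_CALLOSUM: (834.0, 417.0, 1_251.0, 1.199e-3),
    Tissue.DURA: (1_667.0, 1_000.0, 5_000.0, 6e-4),
    Tissue.EYE: (200.0, 100.0, 400.0, 5e-3),
    Tissue.FAT: (2_500.0, 1_250.0, 5_000.0, 4e-4),
    Tissue.MUSCLE: (1_000.0, 200.0, 1_800.0, 1e-3),
    Tissue.SALIVARY_GLANDS: (576.0, 288.0, 864.0, 1.74e-3),
    Tissue.SCALP: (230.0, 115.0, 345.0, 4.35e-3),
    Tissue.SKULL_HARD: (16_000.0, 8_000.0, 40_000.0, 6.25e-5),
    Tissue.SKULL_SOFT: (2_500.0, 1_250.0, 3_750.0, 4e-4),
    Tissue.SOFT_TISSUE: (500.0, 250.0, 750.0, 2e-3),
    Tissue.THALAMUS: (112.0, 56.0, 168.0, 8.93e-3),
}


@dataclass(frozen=True)
class TissueConductivity:
    """Resistivity/conductivity entry for one tissue.

    Resistivities are in Ohm*cm (the units the literature tables use);
    ``mean_conductivity_s_cm`` is the reciprocal of the mean resistivity and
    ``conductivity_s_m`` its SI conversion (1 S/cm = 100 S/m).
    ``printed_conductivity_s_cm`` preserves the rounded literature figure.
    """

    tissue: Tissue
    mean_resistivity_ohm_cm: float
    lower_resistivity_ohm_cm: float
    upper_resistivity_ohm_cm: float
    printed_conductivity_s_cm: float | None = None

    @property
    def mean_conductivity_s_cm(self) -> float:
        return 1.0 / self.mean_resistivity_ohm_cm

    @property
    def conductivity_s_m(self) -> float:
        return 100.0 / self.mean_resistivity_ohm_cm


@dataclass(frozen=True)
class ConductivityTable:
    """Tissue -> conductivity lookup built from a resistivity table."""

    entries: Mapping[Tissue, TissueConductivity]

    def __contains__(self, tissue: Tissue) -> bool:
        return tissue in self.entries

    def __getitem__(self, tissue: Tissue) -> TissueConductivity:
        return self.entries[tissue]

    def conductivity_s_m(self, tissue: Tissue) -> float:
        return self.entries[tissue].conductivity_s_m


def conductivity_from_table(
    rows: Mapping[Tissue, tuple[float, float, float] | tuple[float, float, float, float]],
) -> ConductivityTable:
    """Build a :class:`ConductivityTable` from per-tissue resistivities.

    Parameters
    ----------
    rows
        Mapping tissue -> (mean, lower, upper) resistivity in Ohm*cm, with
        an optional fourth element giving the printed conductivity in S/cm.

    Raises
    ------
    ValidationError
        If any resistivity is non-positive or bounds do not bracket the mean.
    """
    entries: dict[Tissue, TissueConductivity] = {}
    for tissue, row in rows.items():
        mean, lower, upper = row[0], row[1], row[2]
        printed = row[3] if len(row) > 3 else None
        if mean <= 0 or lower <= 0 or upper <= 0:
            raise ValidationError(f"non-positive resistivity for {tissue.name}: {row}")
        if not (lower <= mean <= upper):
            raise ValidationError(
                f"resistivity bounds do not bracket the mean for {tissue.name}: {row}"
            )
        entries[tissue] = TissueConductivity(
            tissue=tissue,
            mean_resistivity_ohm_cm=float(mean),
            lower_resistivity_ohm_cm=float(lower),
            upper_resistivity_ohm_cm=float(upper),
            printed_conductivity_s_cm=printed,
        )
    return ConductivityTable(entries=entries)


def builtin_conductivity_table() -> ConductivityTable:
    """The package's default head-tissue conductivity table."""
    return conductivity_from_table(TABLE1_RESISTIVITIES)


# ---------------------------------------------------------------------------
# Voxel models
# ---------------------------------------------------------------------------


@dataclass
class VoxelModel:
    """A 3-D tissue-label grid with isotropic voxels.

    ``origin`` is the mm position of the center of voxel (0, 0, 0); all mm
    coordinates refer to voxel centers, axis order (x, y, z).
    """

    labels: np.ndarray
    voxel_size: float  # mm per edge
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 3:
            raise ValidationError("label grid must be 3-D")
        if min(self.labels.shape) < 8:
            raise ValidationError("label grid must be at least 8 voxels per axis")
        if self.voxel_size <= 0:
            raise ValidationError("voxel size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis mm coordinates of voxel centers (broadcastable grids)."""
        axes = [
            self.origin[a] + self.voxel_size * np.arange(self.shape[a])
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]

    def positions_mm(self, voxels: np.ndarray) -> np.ndarray:
        """mm center positions of an (N, 3) array of voxel indices."""
        return self.origin[None, :] + self.voxel_size * np.asarray(voxels, dtype=float)

    def center_mm(self) -> np.ndarray:
        """mm position of the geometric grid center."""
        return self.origin + self.voxel_size * (np.asarray(self.shape) - 1) / 2.0

    def count(self, tissue: Tissue) -> int:
        return int(np.count_nonzero(self.labels == int(tissue)))

    def mask(self, tissue: Tissue) -> np.ndarray:
        return self.labels == int(tissue)

    def copy(self) -> "VoxelModel":
        return VoxelModel(self.labels.copy(), self.voxel_size, self.origin.copy())


@dataclass
class ConductivityVolume:
    """Per-voxel conductivity in S/m on the same grid as its label model."""

    sigma: np.ndarray  # S/m
    voxel_size: float  # mm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)


@dataclass(frozen=True)
class Corrugation:
    """Angular corrugation of the white/gray interface emulating gyri/sulci.

    The white-matter outer radius is perturbed by
    ``amplitude * cos(f*theta) * cos(f*phi) * sin(theta)`` where theta is the
    polar angle and phi the azimuth about the phantom center; the ``sin``
    factor keeps the perturbation single-valued at the poles.
    """

    amplitude_mm: float = 0.0
    angular_frequency: int = 8

    def radial_offset(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        f = self.angular_frequency
        return (
            self.amplitude_mm
            * np.cos(f * theta)
            * np.cos(f * phi)
            * np.sin(theta)
        )

    def analytic_normal(self, theta: float, phi: float, radius_mm: float) -> np.ndarray:
        """Outward unit normal of the corrugated surface r = r0 + offset.

        Gradient of F = r - (r0 + c(theta, phi)) in spherical coordinates,
        returned as a Cartesian unit vector.
        """
        a, k = self.amplitude_mm, self.angular_frequency
        dc_dtheta = a * np.cos(k * phi) * (
            -k * np.sin(k * theta) * np.sin(theta)
            + np.cos(k * theta) * np.cos(theta)
        )
        dc_dphi_over_sin = -a * k * np.cos(k * theta) * np.sin(k * phi)
        e_r = np.array(
            [
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta),
            ]
        )
        e_theta = np.array(
            [
                np.cos(theta) * np.cos(phi),
                np.cos(theta) * np.sin(phi),
                -np.sin(theta),
            ]
        )
        e_phi = np.array([-np.sin(phi), np.cos(phi), 0.0])
        grad = (
            e_r
            - (dc_dtheta / radius_mm) * e_theta
            - (dc_dphi_over_sin / radius_mm) * e_phi
        )
        return grad / np.linalg.norm(grad)


def default_head_radii(voxel_size: float) -> list[tuple[Tissue, float]]:
    """Default nested-shell outer radii (mm), innermost first.

    The dura is one voxel thick (the anatomical layer is ~0.8-0.9 mm; a
    single-voxel shell is the thinnest representable analogue).
    """
    dura_outer = 47.0 + voxel_size
    skull_hard = max(53.0, dura_outer + voxel_size)
    skull_soft = max(55.0, skull_hard + voxel_size)
    scalp = max(60.0, skull_soft + voxel_size)
    return [
        (Tissue.WHITE, 40.0),
        (Tissue.GRAY, 44.0),
        (Tissue.CSF, 47.0),
        (Tissue.DURA, dura_outer),
        (Tissue.SKULL_HARD, skull_hard),
        (Tissue.SKULL_SOFT, skull_soft),
        (Tissue.SCALP, scalp),
    ]


def build_shell_phantom(
    layer_radii: Sequence[tuple[Tissue, float]],
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    corrugation: Corrugation | None = None,
    center: np.ndarray | None = None,
    origin: np.ndarray | None = None,
) -> VoxelModel:
    """Build a nested-shell voxel phantom.

    Parameters
    ----------
    layer_radii
        (tissue, outer radius mm) pairs, innermost first, radii strictly
        increasing.  Voxels beyond the last radius are external air.
    grid_shape
        Grid dimensions (voxels per axis).
    voxel_size
        Isotropic voxel edge in mm.
    corrugation
        Optional corrugation of the innermost (white/gray) interface.
    center
        mm position of the phantom center; defaults to the grid center.
    origin
        mm position of voxel (0,0,0); defaults to (0,0,0).

    Raises
    ------
    ConfigurationError
        If radii are not strictly increasing or the corrugation amplitude
        breaks shell nesting.
    GeometryError
        If the phantom (outer radius plus one air voxel margin) does not fit
        inside the grid.
    """
    if len(layer_radii) < 2:
        raise ConfigurationError("need at least two shells")
    radii = np.array([r for _, r in layer_radii], dtype=float)
    if np.any(np.diff(radii) <= 0) or radii[0] <= 0:
        raise ConfigurationError(f"shell radii must be strictly increasing: {radii}")
    corr = corrugation or Corrugation(0.0)
    if corr.amplitude_mm < 0:
        raise ConfigurationError("corrugation amplitude must be non-negative")
    ribbon = radii[1] - radii[0]
    if corr.amplitude_mm >= min(ribbon, radii[0]):
        raise ConfigurationError(
            "corrugation amplitude must be smaller than the second shell's "
            f"thickness ({ribbon} mm) to preserve shell nesting"
        )

    origin_arr = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    model = VoxelModel(
        labels=np.zeros(grid_shape, dtype=np.int16),
        voxel_size=voxel_size,
        origin=origin_arr,
    )
    ctr = model.center_mm() if center is None else np.asarray(center, dtype=float)

    lo = origin_arr
    hi = origin_arr + voxel_size * (np.asarray(grid_shape) - 1)
    margin = radii[-1] + voxel_size
    if np.any(ctr - margin < lo) or np.any(ctr + margin > hi):
        raise GeometryError(
            f"phantom outer radius {radii[-1]} mm (+1 voxel air margin) does "
            f"not fit in the grid around center {ctr}"
        )

    xx, yy, zz = model.voxel_centers_mm()
    dx, dy, dz = xx - ctr[0], yy - ctr[1], zz - ctr[2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)

    thresholds = [None] * len(radii)
    if corr.amplitude_mm > 0:
        with np.errstate(invalid="ignore"):
            theta = np.arccos(np.clip(dz / np.where(r > 0, r, 1.0), -1.0, 1.0))
        phi = np.arctan2(dy, dx)
        thresholds[0] = radii[0] + corr.radial_offset(theta, phi)
    else:
        thresholds[0] = np.full_like(r, radii[0])
    for i in range(1, len(radii)):
        thresholds[i] = radii[i]

    labels = np.full(grid_shape, int(Tissue.AIR_EXTERNAL), dtype=np.int16)
    assigned = np.zeros(grid_shape, dtype=bool)
    for (tissue, _), thr in zip(layer_radii, thresholds):
        band = (~assigned) & (r <= thr)
        labels[band] = int(tissue)
        assigned |= band
    model.labels = labels
    return model


def realize_conductivity(
    model: VoxelModel,
    table: ConductivityTable,
    overrides: Mapping[Tissue, float] | None = None,
) -> ConductivityVolume:
    """Map tissue labels to per-voxel conductivity in S/m.

    ``overrides`` (tissue -> conductivity in S/m) are applied after the
    table lookup; used e.g. for skull-conductivity sensitivity sweeps.

    Raises
    ------
    ValidationError
        If a label present in the model has neither a table entry nor an
        override.
    """
    overrides = dict(overrides or {})
    present = [Tissue(v) for v in np.unique(model.labels)]
    sigma_of: dict[int, float] = {}
    missing = []
    for tissue in present:
        if tissue in overrides:
            sigma_of[int(tissue)] = float(overrides[tissue])
        elif tissue in table:
            sigma_of[int(tissue)] = table.conductivity_s_m(tissue)
        else:
            missing.append(tissue.name)
    if missing:
        raise ValidationError(f"no conductivity for labels: {', '.join(missing)}")

    lut = np.zeros(max(sigma_of) + 1, dtype=float)
    for code, s in sigma_of.items():
        lut[code] = s
    sigma = lut[model.labels]
    return ConductivityVolume(sigma=sigma, voxel_size=model.voxel_size, origin=model.origin.copy())


def replace_tissue(model: VoxelModel, from_tissue: Tissue, to_tissue: Tissue) -> VoxelModel:
    """Relabel every ``from_tissue`` voxel as ``to_tissue`` (pure copy).

    Replacing an absent tissue is a no-op; total voxel count is conserved.
    """
    out = model.copy()
    out.labels[out.labels == int(from_tissue)] = int(to_tissue)
    return out


# ---------------------------------------------------------------------------
# Cortical source model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceConfig:
    """Distributed cortical dipole configuration.

    Magnitudes are i.i.d. uniform on [amplitude_min, amplitude_max] A*m
    (default 0 to 4e-4 A*m = 0.4 mA*m per cortical voxel).
    """

    amplitude_min: float = 0.0
    amplitude_max: float = 4.0e-4
    distribution: str = "uniform"
    seed: int = 0
    normal_smoothing_width_mm: float | None = None  # default: 2 voxels

    def __post_init__(self) -> None:
        if not (0 <= self.amplitude_min <= self.amplitude_max):
            raise ConfigurationError(
                "need 0 <= amplitude_min <= amplitude_max, got "
                f"[{self.amplitude_min}, {self.amplitude_max}]"
            )
        if self.distribution != "uniform":
            raise ConfigurationError(f"unsupported distribution: {self.distribution}")

    def with_seed(self, seed: int) -> "SourceConfig":
        return _dc_replace(self, seed=seed)


@dataclass
class CorticalNormals:
    """Unit white->gray surface normals on gray-matter voxels."""

    voxels: np.ndarray  # (N, 3) int indices of gray voxels
    vectors: np.ndarray  # (N, 3) unit vectors
    radial_fallback: np.ndarray  # (N,) bool, True where the gradient vanished

    @property
    def n_fallback(self) -> int:
        return int(np.count_nonzero(self.radial_fallback))


@dataclass
class DipoleField:
    """One current dipole per cortical voxel."""

    voxels: np.ndarray  # (N, 3) int
    positions_mm: np.ndarray  # (N, 3)
    orientations: np.ndarray  # (N, 3) unit vectors
    magnitudes_a_m: np.ndarray  # (N,) A*m

    def __len__(self) -> int:
        return self.voxels.shape[0]

    @property
    def moments_a_m(self) -> np.ndarray:
        """(N, 3) dipole moment vectors in A*m."""
        return self.orientations * self.magnitudes_a_m[:, None]

    def scaled(self, factor: float) -> "DipoleField":
        return DipoleField(
            voxels=self.voxels.copy(),
            positions_mm=self.positions_mm.copy(),
            orientations=self.orientations.copy(),
            magnitudes_a_m=self.magnitudes_a_m * factor,
        )


def compute_cortical_normals(
    model: VoxelModel,
    smoothing_width_mm: float | None = None,
    center: np.ndarray | None = None,
) -> CorticalNormals:
    """Estimate white->gray surface normals on every gray voxel.

    A Gaussian-smoothed white-matter indicator is differentiated; the
    negated, normalized gradient points from white toward gray.  Gray voxels
    where the smoothed gradient vanishes fall back to the outward radial
    direction from the phantom center and are flagged.

    Parameters
    ----------
    smoothing_width_mm
        Gaussian sigma in mm; default is 2 voxels.
    """
    white = model.mask(Tissue.WHITE)
    gray_idx = np.argwhere(model.mask(Tissue.GRAY))
    if not white.any() or gray_idx.shape[0] == 0:
        raise ValidationError("model must contain both white and gray matter")

    sigma_vox = (
        2.0 if smoothing_width_mm is None else smoothing_width_mm / model.voxel_size
    )
    indicator = ndimage.gaussian_filter(white.astype(float), sigma=sigma_vox)
    grads = np.gradient(indicator, model.voxel_size)

    gi = tuple(gray_idx.T)
    vec = -np.stack([g[gi] for g in grads], axis=1)  # white -> gray
    norms = np.linalg.norm(vec, axis=1)
    tiny = norms < 1e-12 * max(norms.max(), 1e-300)

    if tiny.any():
        ctr = model.center_mm() if center is None else np.asarray(center, dtype=float)
        pos = model.positions_mm(gray_idx[tiny])
        radial = pos - ctr[None, :]
        rn = np.linalg.norm(radial, axis=1)
        rn[rn == 0] = 1.0
        vec[tiny] = radial / rn[:, None]
        norms[tiny] = 1.0
    vec = vec / norms[:, None]
    return CorticalNormals(voxels=gray_idx, vectors=vec, radial_fallback=tiny)


def sample_dipole_field(
    model: VoxelModel,
    normals: CorticalNormals,
    config: SourceConfig,
) -> DipoleField:
    """Draw one dipole per cortical gray voxel.

    Magnitudes are i.i.d. uniform on [amplitude_min, amplitude_max] A*m,
    reproducible from ``config.seed``.

    Raises
    ------
    ValidationError
        If the model has no gray-matter voxels or normals do not cover them.
    """
    n = normals.voxels.shape[0]
    if n == 0:
        raise ValidationError("empty cortex: no gray-matter voxels")
    if n != model.count(Tissue.GRAY):
        raise ValidationError("normals do not cover all cortical voxels")
    rng = np.random.default_rng(config.seed)
    magnitudes = rng.uniform(config.amplitude_min, config.amplitude_max, size=n)
    return DipoleField(
        voxels=normals.voxels.copy(),
        positions_mm=model.positions_mm(normals.voxels),
        orientations=normals.vectors.copy(),
        magnitudes_a_m=magnitudes,
    )
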