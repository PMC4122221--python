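"""Finite-volume solution of the quasi-static volume-conduction problem.

The EEG forward problem at quasi-static frequencies reduces to the Poisson
equation with inhomogeneous conductivity,

    div( sigma grad phi ) = div J_p,

discretized here with a cell-centered finite-volume scheme on the regular
voxel grid: the conductance of the face between two conductive voxels is
the harmonic mean of their conductivities times face area over center
distance (series composition, which correctly limits coupling across thin
resistive layers such as the dura).  Faces to zero-conductivity voxels
carry zero conductance, i.e. a homogeneous Neumann boundary: no current
flows into air.

Each dipole becomes a balanced monopole pair +-I injected one voxel step on
either side of the dipole center along its orientation, with trilinear
splitting onto neighboring voxel centers for oblique orientations.  With
separation d between the two injection points, I = |p| / d, so the discrete
first moment of the injected currents reproduces the dipole moment exactly
(trilinear weights reproduce linear functions).

The resulting system is symmetric positive semidefinite with a
one-dimensional null space (the constant); it is solved with conjugate
gradients under a mean-zero gauge projection applied every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import LinearOperator, cg

from .exceptions import SolverError, ValidationError
from .phantom import ConductivityVolume, DipoleField

__all__ = [
    "VolumeOperator",
    "CurrentSourceVolume",
    "PotentialVolume",
    "FluxField",
    "assemble_system",
    "dipoles_to_currents",
    "solve_potential",
    "compute_flux",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class VolumeOperator:
    """Discrete div(sigma grad .) operator restricted to conductive voxels.

    ``matrix`` maps reduced potentials to net outgoing currents (A):
    (L phi)_i = sum_j g_ij (phi_i - phi_j).  ``index_of`` holds the reduced
    index per grid voxel (-1 outside the conductive region).
    """

    matrix: sparse.csr_matrix
    mask: np.ndarray  # conductive voxels
    index_of: np.ndarray  # grid -> reduced index, int32, -1 where non-conductive
    voxel_size: float  # mm
    origin: np.ndarray
    face_conductances: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, default=None)

    @property
    def n_unknowns(self) -> int:
        return int(self.matrix.shape[0])


@dataclass
class CurrentSourceVolume:
    """Per-voxel injected currents (A) on the grid (dense, mostly zero)."""

    currents: np.ndarray

    @property
    def total(self) -> float:
        return float(self.currents.sum())

    @property
    def l1(self) -> float:
        return float(np.abs(self.currents).sum())


@dataclass
class PotentialVolume:
    """Solved potentials (V) on conductive voxels; NaN elsewhere.

    Gauge: the mean over conductive voxels is zero.
    """

    phi: np.ndarray
    mask: np.ndarray
    voxel_size: float
    origin: np.ndarray
    residual: float = 0.0
    iterations: int = 0

    def values_at(self, voxels: np.ndarray) -> np.ndarray:
        return self.phi[tuple(np.asarray(voxels).T)]


def _face_conductance(sigma: np.ndarray, axis: int, voxel_size_m: float) -> np.ndarray:
    """Harmonic-mean face conductances (S) along one axis.

    Shape is the grid with one fewer voxel along ``axis``; the face area is
    h^2 and the center distance h, so g = sigma_harm * h.
    """
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    a = sigma[tuple(sl_lo)]
    b = sigma[tuple(sl_hi)]
    s = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        harm = np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)
    return harm * voxel_size_m


def assemble_system(sigma: ConductivityVolume) -> VolumeOperator:
    """Assemble the symmetric finite-volume operator over conductive voxels.

    Raises
    ------
    ValidationError
        If conductivities are negative, no voxel is conductive, or the
        conductive region splits into several 6-connected components (the
        mean-zero gauge would be ill-defined per component).
    """
    sig = np.asarray(sigma.sigma, dtype=float)
    if np.any(sig < 0):
        raise ValidationError("conductivities must be non-negative")
    mask = sig > 0
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("no conductive voxels")
    labels, n_comp = ndimage.label(mask, structure=_STRUCT6)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        raise ValidationError(
            f"conductive region has {n_comp} disconnected components "
            f"(sizes {sorted(sizes.tolist(), reverse=True)})"
        )

    index_of = np.full(sig.shape, -1, dtype=np.int32)
    index_of[mask] = np.arange(n, dtype=np.int32)
    h_m = sigma.voxel_size * 1e-3

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    g_faces = []
    for axis in range(3):
        g = _face_conductance(sig, axis, h_m)
        g_faces.append(g)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        i_lo = index_of[tuple(sl_lo)]
        i_hi = index_of[tuple(sl_hi)]
        live = (g > 0) & (i_lo >= 0) & (i_hi >= 0)
        gl = g[live]
        a = i_lo[live]
        b = i_hi[live]
        rows.append(a)
        cols.append(b)
        vals.append(-gl)
        rows.append(b)
        cols.append(a)
        vals.append(-gl)
        np.add.at(diag, a, gl)
        np.add.at(diag, b, gl)

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    L = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return VolumeOperator(
        matrix=L,
        mask=mask,
        index_of=index_of,
        voxel_size=sigma.voxel_size,
        origin=np.asarray(sigma.origin, dtype=float).copy(),
        face_conductances=tuple(g_faces),
    )


def dipoles_to_currents(
    dipoles: DipoleField,
    operator: VolumeOperator,
) -> CurrentSourceVolume:
    """Discretize dipoles as balanced monopole pairs on the voxel grid.

    For each dipole of moment p at center x with unit orientation u, a
    current +I is injected at x + h*u and -I at x - h*u (h = voxel edge),
    each deposited onto the 8 surrounding voxel centers with trilinear
    weights.  With separation d = 2h between the injection points,
    I = |p| / d, which makes the discrete current distribution's first
    moment equal to p exactly.

    Raises
    ------
    ValidationError
        If any injection weight falls on a non-conductive voxel.
    """
    shape = operator.mask.shape
    h = operator.voxel_size  # mm
    h_m = h * 1e-3
    currents = np.zeros(shape)
    if len(dipoles) == 0:
        return CurrentSourceVolume(currents=currents)

    nonzero = dipoles.magnitudes_a_m > 0
    pos = dipoles.positions_mm[nonzero]
    ori = dipoles.orientations[nonzero]
    mags = dipoles.magnitudes_a_m[nonzero]
    if pos.shape[0] == 0:
        return CurrentSourceVolume(currents=currents)

    intensity = mags / (2.0 * h_m)  # I = |p| / d, d = 2h
    offenders: list[tuple[int, int, int]] = []
    for sign in (+1.0, -1.0):
        # continuous voxel coordinates of the injection points
        cont = (pos + sign * h * ori - operator.origin[None, :]) / h
        base = np.floor(cont).astype(int)
        frac = cont - base
        for corner in range(8):
            off = np.array([(corner >> a) & 1 for a in range(3)])
            idx = base + off[None, :]
            w = np.prod(
                np.where(off[None, :] == 1, frac, 1.0 - frac), axis=1
            )
            keep = w > 1e-15
            if not keep.any():
                continue
            idxk = idx[keep]
            if np.any((idxk < 0) | (idxk >= np.array(shape)[None, :])):
                raise ValidationError("dipole injection point falls outside the grid")
            conductive = operator.mask[tuple(idxk.T)]
            if not conductive.all():
                bad = idxk[~conductive]
                offenders.extend(map(tuple, bad[:10]))
                continue
            np.add.at(
                currents,
                tuple(idxk.T),
                sign * intensity[keep] * w[keep],
            )
    if offenders:
        raise ValidationError(
            f"dipole injection currents fall in non-conductive voxels, e.g. {offenders[:5]}"
        )
    return CurrentSourceVolume(currents=currents)


def solve_potential(
    operator: VolumeOperator,
    sources: CurrentSourceVolume,
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> PotentialVolume:
    """Solve L phi = I by preconditioned conjugate gradients.

    The pure-Neumann operator is singular with a constant null space; the
    gauge is fixed by projecting out the mean every iteration and the
    right-hand side must be balanced (|sum I| <= 1e-9 of its L1 norm).
    The returned potential has zero mean over conductive voxels.

    Raises
    ------
    SolverError
        On source imbalance or failure to reach the requested relative
        residual within ``max_iter`` iterations.
    """
    L = operator.matrix
    n = L.shape[0]
    b = sources.currents[operator.mask]
    l1 = float(np.abs(b).sum())
    if l1 > 0 and abs(float(b.sum())) > 1e-9 * l1:
        raise SolverError(
            f"unbalanced sources: net current {b.sum():.3e} A vs L1 norm {l1:.3e} A"
        )
    if l1 == 0:
        phi = np.full(operator.mask.shape, np.nan)
        phi[operator.mask] = 0.0
        return PotentialVolume(
            phi=phi,
            mask=operator.mask,
            voxel_size=operator.voxel_size,
            origin=operator.origin.copy(),
        )

    def project(v: np.ndarray) -> np.ndarray:
        return v - v.mean()

    def matvec(v: np.ndarray) -> np.ndarray:
        return project(L @ project(v))

    A = LinearOperator((n, n), matvec=matvec, dtype=float)
    d = L.diagonal()
    d[d <= 0] = 1.0
    inv_d = 1.0 / d
    M = LinearOperator((n, n), matvec=lambda v: project(inv_d * v), dtype=float)
    b0 = project(b)

    it_count = 0

    def callback(_xk: np.ndarray) -> None:
        nonlocal it_count
        it_count += 1

    x, info = cg(A, b0, rtol=tol * 0.1, atol=0.0, maxiter=max_iter, M=M, callback=callback)
    x = project(x)
    residual = float(np.linalg.norm(L @ x - b0) / np.linalg.norm(b0))
    if residual > tol:
        raise SolverError(
            f"CG did not converge: relative residual {residual:.3e} > {tol:.1e} "
            f"after {it_count} iterations (info={info})"
        )
    phi = np.full(operator.mask.shape, np.nan)
    phi[operator.mask] = x
    return PotentialVolume(
        phi=phi,
        mask=operator.mask,
        voxel_size=operator.voxel_size,
        origin=operator.origin.copy(),
        residual=residual,
        iterations=it_count,
    )


@dataclass
class FluxField:
    """Signed face currents (A) along each axis; entry f of axis a is the
    current flowing from voxel i to voxel i+1 along a."""

    face_currents: tuple[np.ndarray, np.ndarray, np.ndarray]
    voxel_size: float

    def divergence(self) -> np.ndarray:
        """Net outgoing current per voxel (A); equals injected current."""
        f0 = self.face_currents[0]
        grid_shape = (f0.shape[0] + 1, f0.shape[1], f0.shape[2])
        div = np.zeros(grid_shape)
        for axis, f in enumerate(self.face_currents):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(None, -1)
            sl_hi[axis] = slice(1, None)
            div[tuple(sl_lo)] += f  # current leaving voxel i toward i+1
            div[tuple(sl_hi)] -= f  # same current entering voxel i+1
        return div

    def magnitude_volume(self) -> np.ndarray:
        """Voxel-center current-density magnitude (A/m^2), for export."""
        area = (self.voxel_size * 1e-3) ** 2
        out = None
        for axis, f in enumerate(self.face_currents):
            pad_lo = [(0, 0)] * 3
            pad_hi = [(0, 0)] * 3
            pad_lo[axis] = (1, 0)
            pad_hi[axis] = (0, 1)
            centered = 0.5 * (np.pad(f, pad_lo) + np.pad(f, pad_hi)) / area
            out = centered**2 if out is None else out + centered**2
        return np.sqrt(out)


def compute_flux(operator: VolumeOperator, potential: PotentialVolume) -> FluxField:
    """Face currents -g * (phi_j - phi_i) of a solved potential."""
    phi = np.where(operator.mask, np.nan_to_num(potential.phi), 0.0)
    faces = []
    for axis, g in enumerate(operator.face_conductances):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        faces.append(g * (phi[tuple(sl_lo)] - phi[tuple(sl_hi)]))
    return FluxField(face_currents=tuple(faces), voxel_size=operator.voxel_size)
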