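"""Analytic dipole potential in concentric spherical shells.

A current dipole inside an N-shell piecewise-homogeneous sphere (insulating
exterior) has a classical solution by separation of variables: per Legendre
degree n the potential in shell j is a combination of r^n and r^-(n+1)
radial modes, matched across interfaces by continuity of potential and of
radial current density sigma * dphi/dr, with zero radial current at the
outer surface.  The dipole's free-space field supplies the particular
solution in its host shell; decomposing the moment into radial and
tangential parts reduces the problem to azimuthal orders m = 0 and m = 1.

This series is the independent oracle against which the finite-volume
solver is validated.  All quantities are SI (m, S/m, A*m, V).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import lpmv

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "ShellSpec",
    "multishell_potential",
    "attenuation_ratio",
    "fibonacci_sphere_points",
]


@dataclass(frozen=True)
class ShellSpec:
    """Concentric shells: outer radii (m, strictly increasing) and
    conductivities (S/m, innermost outward)."""

    radii: tuple[float, ...]
    conductivities: tuple[float, ...]

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        sigmas = tuple(float(s) for s in self.conductivities)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "conductivities", sigmas)
        if len(radii) != len(sigmas) or len(radii) == 0:
            raise ConfigurationError("radii and conductivities must have equal, nonzero length")
        if any(np.diff(radii) <= 0) or radii[0] <= 0:
            raise ConfigurationError(f"shell radii must be strictly increasing: {radii}")
        if any(s <= 0 for s in sigmas):
            raise ConfigurationError("shell conductivities must be positive")

    @property
    def n_shells(self) -> int:
        return len(self.radii)

    def to_dict(self) -> dict:
        return {"radii_m": list(self.radii), "conductivities_s_m": list(self.conductivities)}

    @classmethod
    def from_dict(cls, data: dict) -> "ShellSpec":
        return cls(tuple(data["radii_m"]), tuple(data["conductivities_s_m"]))

    def with_conductivity(self, shell_index: int, sigma: float) -> "ShellSpec":
        sigmas = list(self.conductivities)
        sigmas[shell_index] = sigma
        return ShellSpec(self.radii, tuple(sigmas))


def fibonacci_sphere_points(n: int, radius: float = 1.0) -> np.ndarray:
    """Near-uniform (Fibonacci spiral) point set on a sphere, shape (n, 3)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z * z)
    return radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _host_shell(b: float, radii: tuple[float, ...]) -> int:
    """Index of the shell containing radius b (error if on an interface)."""
    eps = 1e-9 * radii[-1]
    for j, r in enumerate(radii):
        if abs(b - r) < eps:
            raise ValidationError(f"dipole radius {b} m lies on shell interface {r} m")
        if b < r:
            return j
    raise ValidationError(f"dipole radius {b} m lies outside the outer shell {radii[-1]} m")


def _assemble_matrix(n: int, shells: ShellSpec) -> np.ndarray:
    """Interface-matching matrix for degree n.

    Unknown layout: [alpha_1, alpha_2, beta_2, ..., alpha_N, beta_N] with
    per-shell basis u_j = (r/r_j)^n and v_j = (r_{j-1}/r)^(n+1) (scaled so
    every matrix entry is O(1) regardless of n).  The matrix is the same
    for azimuthal orders m = 0 and m = 1; only the source vector differs.
    """
    radii = shells.radii
    sig = shells.conductivities
    N = len(radii)
    dim = 2 * N - 1

    def col_alpha(j: int) -> int:
        return 0 if j == 0 else 2 * j - 1

    def col_beta(j: int) -> int:
        return 2 * j  # only valid for j >= 1

    A = np.zeros((dim, dim))
    row = 0
    for i in range(N - 1):  # interface at radii[i] between shells i and i+1
        r = radii[i]
        # basis values for shell i at its outer radius
        u_i, du_i = 1.0, n / r
        if i == 0:
            v_i = dv_i = None
        else:
            v_i = (radii[i - 1] / r) ** (n + 1)
            dv_i = -(n + 1) / r * v_i
        # basis values for shell i+1 at its inner radius
        u_o = (r / radii[i + 1]) ** n
        du_o = n / r * u_o
        v_o, dv_o = 1.0, -(n + 1) / r

        A[row, col_alpha(i)] = u_i
        if v_i is not None:
            A[row, col_beta(i)] = v_i
        A[row, col_alpha(i + 1)] = -u_o
        A[row, col_beta(i + 1)] = -v_o
        row += 1

        A[row, col_alpha(i)] = sig[i] * du_i
        if dv_i is not None:
            A[row, col_beta(i)] = sig[i] * dv_i
        A[row, col_alpha(i + 1)] = -sig[i + 1] * du_o
        A[row, col_beta(i + 1)] = -sig[i + 1] * dv_o
        row += 1

    # outer boundary: zero radial current at radii[-1]
    r = radii[-1]
    A[row, col_alpha(N - 1)] = sig[-1] * n / r
    if N > 1:
        A[row, col_beta(N - 1)] = sig[-1] * (-(n + 1) / r) * (radii[-2] / r) ** (n + 1)
    else:
        pass  # single shell: only alpha_1
    return A


def _assemble_rhs(n: int, shells: ShellSpec, b: float, s: int, c_out: float, c_in: float) -> np.ndarray:
    """RHS of the matching system for source constants (c_out, c_in).

    The particular solution in host shell s has radial profile
    F_out(r) = c_out * b^(n-1) * r^-(n+1) for r > b and
    F_in(r)  = c_in  * r^n * b^-(n+2)    for r < b.
    """
    radii = shells.radii
    sig = shells.conductivities
    N = len(radii)
    rhs = np.zeros(2 * N - 1)

    def f_out(r: float) -> tuple[float, float]:
        val = c_out * b ** (n - 1) * r ** -(n + 1)
        return val, -(n + 1) / r * val

    def f_in(r: float) -> tuple[float, float]:
        val = c_in * r**n * b ** -(n + 2)
        return val, n / r * val

    row = 0
    for i in range(N - 1):
        r = radii[i]
        src_i = f_out(r) if i == s else None  # r_i >= b when shell i hosts
        src_o = f_in(r) if i + 1 == s else None  # r_i <= b when shell i+1 hosts
        phi_rhs = 0.0
        cur_rhs = 0.0
        if src_o is not None:
            phi_rhs += src_o[0]
            cur_rhs += sig[s] * src_o[1]
        if src_i is not None:
            phi_rhs -= src_i[0]
            cur_rhs -= sig[s] * src_i[1]
        rhs[row] = phi_rhs
        rhs[row + 1] = cur_rhs
        row += 2
    if s == N - 1:
        _, dF = f_out(radii[-1])
        rhs[row] = -sig[-1] * dF
    return rhs


def multishell_potential(
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    shells: ShellSpec,
    surface_points: np.ndarray,
    n_terms: int = 60,
) -> np.ndarray:
    """Series potential of a current dipole in concentric conductive shells.

    Parameters
    ----------
    dipole_position, dipole_moment
        SI position (m) and moment (A*m) of the dipole; the position must
        lie strictly inside a shell (not on an interface).
    surface_points
        (M, 3) evaluation points (m); conventionally on the outer radius,
        but any point inside the outermost shell is accepted.
    n_terms
        Legendre degrees 1..n_terms.

    Returns
    -------
    (M,) potentials in volts.  The n >= 1 series carries no monopole term,
    so the potential averages to zero over any full sphere concentric with
    the shells; comparisons against average-referenced numerical solutions
    are gauge-consistent after both sides are referenced over the same
    point set.

    Warns if the last term still contributes more than 1e-8 of the running
    sum (series not converged at ``n_terms``).
    """
    if n_terms < 1:
        raise ConfigurationError("n_terms must be >= 1")
    r0 = np.asarray(dipole_position, dtype=float).reshape(3)
    p = np.asarray(dipole_moment, dtype=float).reshape(3)
    pts = np.atleast_2d(np.asarray(surface_points, dtype=float))
    b = float(np.linalg.norm(r0))
    s = _host_shell(b, shells.radii)
    sigma_s = shells.conductivities[s]

    # Rotated frame: e_z along the dipole position (or global z at center),
    # e_x along the tangential moment component.
    if b > 0:
        e_z = r0 / b
    else:
        e_z = np.array([0.0, 0.0, 1.0])
    p_r = float(p @ e_z)
    p_t_vec = p - p_r * e_z
    p_t = float(np.linalg.norm(p_t_vec))
    # a tangential residual below rounding noise is treated as purely radial
    if p_t <= 1e-12 * float(np.linalg.norm(p)):
        p_t = 0.0
    if p_t > 0:
        e_x = p_t_vec / p_t
        e_x = e_x - (e_x @ e_z) * e_z
        e_x /= np.linalg.norm(e_x)
    else:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e_z @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e_x = helper - (helper @ e_z) * e_z
        e_x /= np.linalg.norm(e_x)
    e_y = np.cross(e_z, e_x)

    xl = pts @ e_x
    yl = pts @ e_y
    zl = pts @ e_z
    r = np.sqrt(xl * xl + yl * yl + zl * zl)
    if np.any(r > shells.radii[-1] * (1 + 1e-9)):
        raise ValidationError("evaluation points must lie inside the outer shell")
    r = np.minimum(r, shells.radii[-1])
    cos_theta = np.clip(zl / np.where(r > 0, r, 1.0), -1.0, 1.0)
    cos_phi = np.where(
        np.hypot(xl, yl) > 0, xl / np.where(np.hypot(xl, yl) > 0, np.hypot(xl, yl), 1.0), 0.0
    )

    # Evaluation shell per point (points may sit in any shell).
    shell_of_pt = np.searchsorted(shells.radii, r, side="left")
    shell_of_pt = np.minimum(shell_of_pt, shells.n_shells - 1)

    radii = shells.radii
    inner_radius = np.array([0.0] + list(radii[:-1]))

    phi_total = np.zeros(pts.shape[0])
    prev_abs = np.zeros(pts.shape[0])
    last_rel = 0.0
    four_pi_sigma = 4.0 * np.pi * sigma_s

    for n in range(1, n_terms + 1):
        A = _assemble_matrix(n, shells)
        # m = 0 (radial moment): c_out = p_r*n/(4 pi sigma), c_in = -p_r*(n+1)/(4 pi sigma)
        # m = 1 (tangential):    c_out = p_t/(4 pi sigma),   c_in = p_t/(4 pi sigma)
        coef0 = coef1 = None
        if p_r != 0.0:
            rhs0 = _assemble_rhs(n, shells, b, s, p_r * n / four_pi_sigma, -p_r * (n + 1) / four_pi_sigma)
            coef0 = np.linalg.solve(A, rhs0)
        if p_t != 0.0:
            rhs1 = _assemble_rhs(n, shells, b, s, p_t / four_pi_sigma, p_t / four_pi_sigma)
            coef1 = np.linalg.solve(A, rhs1)

        # radial profiles at evaluation points
        def radial_profile(coef: np.ndarray, c_out: float, c_in: float) -> np.ndarray:
            j = shell_of_pt
            alpha = np.where(j == 0, coef[0], coef[np.maximum(2 * j - 1, 0)])
            beta = np.where(j == 0, 0.0, coef[np.minimum(2 * j, coef.size - 1)])
            rj = np.asarray(radii)[j]
            rjm = inner_radius[j]
            with np.errstate(divide="ignore", invalid="ignore"):
                u = (r / rj) ** n
                v = np.where(r > 0, (rjm / np.maximum(r, 1e-300)) ** (n + 1), 0.0)
            prof = alpha * u + beta * v
            host = j == s
            if host.any():
                above = host & (r >= b)
                below = host & (r < b)
                if above.any():
                    prof[above] += c_out * b ** (n - 1) * r[above] ** -(n + 1)
                if below.any():
                    prof[below] += c_in * r[below] ** n * b ** -(n + 2)
            return prof

        term = np.zeros(pts.shape[0])
        if coef0 is not None:
            term += radial_profile(
                coef0, p_r * n / four_pi_sigma, -p_r * (n + 1) / four_pi_sigma
            ) * lpmv(0, n, cos_theta)
        if coef1 is not None:
            # P_n^1 without the Condon-Shortley phase: -lpmv(1, n, x)
            term += (
                radial_profile(coef1, p_t / four_pi_sigma, p_t / four_pi_sigma)
                * (-lpmv(1, n, cos_theta))
                * cos_phi
            )
        phi_total += term
        prev_abs += np.abs(term)
        scale = np.max(prev_abs)
        last_rel = np.max(np.abs(term)) / scale if scale > 0 else 0.0

    if last_rel > 1e-8:
        warnings.warn(
            f"multishell series not converged at n_terms={n_terms}: "
            f"last-term contribution {last_rel:.2e}",
            RuntimeWarning,
            stacklevel=2,
        )
    return phi_total


def attenuation_ratio(
    shells_with_layer: ShellSpec,
    shells_layer_replaced: ShellSpec,
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    surface_points: np.ndarray,
    n_terms: int = 60,
) -> float:
    """Root-sum-square surface-potential ratio, replaced-layer over layered.

    The two shell specs must share geometry and differ in conductivity
    only; a ratio > 1 means the replaced (e.g. dura -> CSF) model produces
    larger surface potentials, i.e. the original layer attenuates.
    """
    if shells_with_layer.radii != shells_layer_replaced.radii:
        raise ConfigurationError("shell geometries differ; only conductivity may change")
    v_with = multishell_potential(
        dipole_position, dipole_moment, shells_with_layer, surface_points, n_terms
    )
    v_repl = multishell_potential(
        dipole_position, dipole_moment, shells_layer_replaced, surface_points, n_terms
    )
    denom = float(np.linalg.norm(v_with))
    if denom == 0:
        raise ValidationError("layered model produced zero surface potentials")
    return float(np.linalg.norm(v_repl)) / denom
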