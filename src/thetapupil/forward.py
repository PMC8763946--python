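"""Analytic three-shell spherical head model and leadfield computation.

The forward problem is solved for a current dipole inside the innermost
compartment of three concentric spheres (brain, skull, scalp) with piecewise
constant conductivity.  In each shell the potential for spherical-harmonic
degree ``n`` is ``A r^n + B r^-(n+1)``; coefficients follow from continuity
of the potential and of the radial current density at the two interfaces and
from the insulating boundary at the scalp surface.  The per-degree linear
systems are solved with radii normalised to the scalp radius, which keeps the
powers well conditioned up to the series truncation degree.

With all conductivities equal the solver reduces to the classic homogeneous
sphere result, where the surface coefficient of degree ``n`` equals
``(2n + 1)/n`` — used as an exact oracle in the tests.

Conventions: positions in metres, centred on the sphere centre, x right /
y anterior / z superior; dipole moments in A·m; potentials in volts,
average-referenced across the electrode array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HeadModel", "Leadfield", "shell_coefficients", "compute_leadfield"]


@dataclass(frozen=True)
class HeadModel:
    """Concentric three-sphere volume conductor.

    Default radii 8.7 / 9.2 / 10.0 cm and conductivities 0.33 / 0.0042 /
    0.33 S/m (brain / skull / scalp).
    """

    radii: tuple[float, float, float] = (0.087, 0.092, 0.100)
    sigmas: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, float)
        s = np.asarray(self.sigmas, float)
        if not (np.all(np.diff(r) > 0) and np.all(r > 0)):
            raise ValueError("shell radii must be positive and strictly increasing")
        if not np.all(s > 0):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]


@dataclass
class Leadfield:
    """Forward solutions on a regular source grid.

    ``gain`` has shape (n_voxels, 3, n_channels): scalp potential per unit
    dipole moment along x/y/z at each grid point, average-referenced.
    """

    grid: np.ndarray
    gain: np.ndarray
    spacing: float
    head: HeadModel
    ch_names: list[str] = field(default_factory=list)
    ch_pos: np.ndarray | None = None  # unit-sphere electrode directions

    @property
    def n_voxels(self) -> int:
        return self.grid.shape[0]


def shell_coefficients(head: HeadModel, n_max: int) -> np.ndarray:
    """Surface potential coefficients ``S_n`` for degrees 1..n_max.

    ``S_n`` multiplies the primary (infinite-medium) coefficient of degree
    ``n``: the scalp-surface potential of that degree equals ``S_n`` times
    the coefficient of ``r^-(n+1)`` of the source expansion, with radii
    expressed in units of the scalp radius.  For a homogeneous sphere
    ``S_n = (2n + 1)/n``.
    """
    r = np.asarray(head.radii, float) / head.scalp_radius  # (x1, x2, 1)
    s1, s2, s3 = head.sigmas
    x1, x2 = r[0], r[1]
    out = np.empty(n_max + 1)
    out[0] = 0.0
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3 ; source term c=1 on x^-(n+1) in shell 1
        m = np.zeros((5, 5))
        rhs = np.zeros(5)
        # potential continuity at x1
        m[0] = [x1**n, -(x1**n), -(x1 ** -(n + 1)), 0.0, 0.0]
        rhs[0] = -(x1 ** -(n + 1))
        # radial current continuity at x1
        m[1] = [
            s1 * n * x1 ** (n - 1),
            -s2 * n * x1 ** (n - 1),
            s2 * (n + 1) * x1 ** -(n + 2),
            0.0,
            0.0,
        ]
        rhs[1] = s1 * (n + 1) * x1 ** -(n + 2)
        # potential continuity at x2
        m[2] = [0.0, x2**n, x2 ** -(n + 1), -(x2**n), -(x2 ** -(n + 1))]
        # radial current continuity at x2
        m[3] = [
            0.0,
            s2 * n * x2 ** (n - 1),
            -s2 * (n + 1) * x2 ** -(n + 2),
            -s3 * n * x2 ** (n - 1),
            s3 * (n + 1) * x2 ** -(n + 2),
        ]
        # insulating outer boundary at x = 1
        m[4] = [0.0, 0.0, 0.0, s3 * n, -s3 * (n + 1)]
        sol = np.linalg.solve(m, rhs)
        out[n] = sol[3] + sol[4]  # A3 + B3 at x = 1
    return out


def _legendre_sums(
    cos_gamma: np.ndarray, w_p: np.ndarray, w_dp: np.ndarray, n_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate ``sum_n w_p[v,n] P_n(x)`` and ``sum_n w_dp[v,n] P'_n(x)``.

    ``cos_gamma`` is (V, C); weights are (V, n_max+1).  Uses the stable
    three-term recurrences for P_n and P'_n (no division by sin(gamma)).
    """
    x = cos_gamma
    p_prev = np.ones_like(x)  # P_0
    p_cur = x.copy()  # P_1
    dp_prev = np.zeros_like(x)  # P'_0
    dp_cur = np.ones_like(x)  # P'_1
    acc_p = w_p[:, 1:2] * p_cur
    acc_dp = w_dp[:, 1:2] * dp_cur
    for n in range(1, n_max):
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        acc_p += w_p[:, n + 1 : n + 2] * p_next
        acc_dp += w_dp[:, n + 1 : n + 2] * dp_next
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
    return acc_p, acc_dp


def _tangent_basis(unit_dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangential directions per unit vector (V, 3)."""
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (unit_dirs.shape[0], 1))
    near_pole = np.abs(unit_dirs[:, 2]) > 0.9
    ref[near_pole] = [1.0, 0.0, 0.0]
    t1 = np.cross(ref, unit_dirs)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(unit_dirs, t1)
    return t1, t2


def dipole_potentials(
    head: HeadModel,
    dipole_pos: np.ndarray,
    electrode_pos: np.ndarray,
    n_max: int = 60,
) -> np.ndarray:
    """Scalp potentials (V) for unit x/y/z dipoles at each source position.

    Parameters
    ----------
    dipole_pos : (V, 3) positions in metres, strictly inside the brain shell.
    electrode_pos : (C, 3) electrode positions on the scalp sphere (only the
        direction is used; electrodes are assumed on the outer surface).

    Returns
    -------
    (V, 3, C) raw (not re-referenced) surface potentials per unit A·m.
    """
    center = np.asarray(head.center, float)
    src = np.atleast_2d(np.asarray(dipole_pos, float)) - center
    elec = np.asarray(electrode_pos, float) - center
    elec_u = elec / np.linalg.norm(elec, axis=1, keepdims=True)

    b = np.linalg.norm(src, axis=1)
    if np.any(b >= head.brain_radius):
        raise ValueError("dipole outside the brain compartment")
    b_norm = b / head.scalp_radius

    # direction of each source; arbitrary axis for a central source (its
    # tangential/radial split is degenerate but the n=1 term is isotropic).
    src_u = np.where(
        b[:, None] > 1e-12, src / np.maximum(b[:, None], 1e-300), [0.0, 0.0, 1.0]
    )
    t1, t2 = _tangent_basis(src_u)

    n = np.arange(n_max + 1, dtype=float)
    s_n = shell_coefficients(head, n_max)
    # b^(n-1) with the n=1 term defined as 1 also for b = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        b_pow = b_norm[:, None] ** np.maximum(n[None, :] - 1, 0.0)
    w_rad = s_n[None, :] * n[None, :] * b_pow  # weight on P_n
    w_tan = s_n[None, :] * b_pow  # weight on P'_n

    cos_gamma = np.clip(src_u @ elec_u.T, -1.0, 1.0)
    sum_rad, sum_tan = _legendre_sums(cos_gamma, w_rad, w_tan, n_max)

    k = 1.0 / (4.0 * np.pi * head.sigmas[0] * head.scalp_radius**2)
    v_rad = k * sum_rad  # (V, C) potential of unit radial dipole
    # tangential: P_n^1(cos g) cos(beta_j) = P'_n(cos g) * (e_u . t_j)
    v_t1 = k * sum_tan * (t1 @ elec_u.T)
    v_t2 = k * sum_tan * (t2 @ elec_u.T)

    # compose x/y/z orientations from the local radial/tangential basis
    out = (
        src_u[:, :, None] * v_rad[:, None, :]
        + t1[:, :, None] * v_t1[:, None, :]
        + t2[:, :, None] * v_t2[:, None, :]
    )
    return out


def make_source_grid(head: HeadModel, spacing: float = 0.01) -> np.ndarray:
    """Regular grid (V, 3) of source positions strictly inside the brain shell.

    Points closer than half a grid step to the inner-shell surface are
    excluded so every dipole is a valid series source.
    """
    r = head.brain_radius
    ax = np.arange(-r, r + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    keep = np.linalg.norm(pts, axis=1) <= r - spacing / 2
    return pts[keep] + np.asarray(head.center, float)


def compute_leadfield(
    head: HeadModel,
    electrode_pos: np.ndarray,
    spacing: float = 0.01,
    ch_names: list[str] | None = None,
    n_max: int = 60,
) -> Leadfield:
    """Average-referenced leadfield on a regular grid inside the brain shell.

    ``electrode_pos`` may be unit vectors (a montage); they are projected to
    the scalp sphere.  Gain units: V per A·m.
    """
    elec_u = np.asarray(electrode_pos, float)
    elec_u = elec_u / np.linalg.norm(elec_u, axis=1, keepdims=True)
    elec = elec_u * head.scalp_radius
    grid = make_source_grid(head, spacing)
    gain = dipole_potentials(head, grid, elec, n_max=n_max)
    gain -= gain.mean(axis=2, keepdims=True)  # average reference
    names = list(ch_names) if ch_names is not None else [
        f"E{i + 1:02d}" for i in range(elec.shape[0])
    ]
    return Leadfield(
        grid=grid, gain=gain, spacing=spacing, head=head, ch_names=names, ch_pos=elec_u
    )
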