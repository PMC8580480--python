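"""Coarse 3D solver for droplets in non-spherically-symmetric environments.

The radial solvers assume an isolated droplet centred in a spherical domain.
Real droplets sediment onto a passivated coverslip (a no-flux plane that
halves the dilute-phase supply) and often sit next to unbleached neighbours
(extra reservoirs that speed recovery up).  This module solves the same
diffuse-interface equation on a Cartesian box — conservative finite volumes
on a uniform grid, Crank-Nicolson stepping with a conjugate-gradient solve —
to quantify those environment effects and to show that the boundary-trace
fit of D_in is insensitive to them.

The coverslip is the box face z = 0 (every outer face is no-flux, so a
sessile droplet is simply placed with its centre a height h >= R above it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .image_pipeline import ProfileStack, azimuthal_average
from .model_core import ModelParams, diffusivity_of_phi

__all__ = [
    "GeometrySpec",
    "CartesianField",
    "build_phi_tot_3d",
    "bleach_init",
    "solve_full_model_3d",
    "droplet_average_recovery",
    "midplane_stack",
    "recovery_slowdown_factor",
]


@dataclass(frozen=True)
class GeometrySpec:
    """Droplet arrangement inside a closed no-flux box.

    ``centers``/``radii`` define tanh spheres (um); ``bleached`` marks which
    droplets start fully bleached.  ``box`` is the domain extent
    (Lx, Ly, Lz), spanning [0, Lx] x [0, Ly] x [0, Lz]; the face z = 0 plays
    the role of the coverslip when ``coverslip=True`` (it is a no-flux plane
    either way; the flag only enables the h >= R sanity check).
    """

    centers: tuple
    radii: tuple
    bleached: tuple
    box: tuple
    spacing: float
    coverslip: bool = False

    def __post_init__(self) -> None:
        centers = tuple(tuple(float(v) for v in c) for c in self.centers)
        radii = tuple(float(r) for r in self.radii)
        bleached = tuple(bool(b) for b in self.bleached)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "bleached", bleached)
        if not (len(centers) == len(radii) == len(bleached) >= 1):
            raise ValueError("need matching centers, radii and bleach flags")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        for (x, y, z), R in zip(centers, radii):
            if not (
                R <= x <= self.box[0] - R
                and R <= y <= self.box[1] - R
                and R <= z <= self.box[2] - R
            ):
                raise ValueError("droplet does not fit inside the box")
            if self.coverslip and z < R:
                raise ValueError("sessile droplet centre must satisfy h >= R")
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.linalg.norm(np.subtract(centers[i], centers[j]))
                if d < radii[i] + radii[j]:
                    raise ValueError("droplets overlap")

    def cell_centers(self):
        nx, ny, nz = (int(round(b / self.spacing)) for b in self.box)
        xs = (np.arange(nx) + 0.5) * self.spacing
        ys = (np.arange(ny) + 0.5) * self.spacing
        zs = (np.arange(nz) + 0.5) * self.spacing
        return xs, ys, zs


@dataclass
class CartesianField:
    """Time series of the unbleached concentration on the box grid.

    ``values[k]`` has shape (nz, ny, nx); ``phi`` is the static equilibrium
    profile on the same grid.
    """

    spec: GeometrySpec
    times: np.ndarray
    values: np.ndarray  # (nt, nz, ny, nx)
    phi: np.ndarray

    def total_mass(self) -> np.ndarray:
        return self.values.reshape(self.times.size, -1).sum(axis=1) * self.spec.spacing**3


def build_phi_tot_3d(spec: GeometrySpec, params: ModelParams) -> np.ndarray:
    """Equilibrium profile: superposed tanh spheres, clipped at phi_in."""
    xs, ys, zs = spec.cell_centers()
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    phi = np.full(X.shape, params.phi_out)
    for (cx, cy, cz), R in zip(spec.centers, spec.radii):
        dist = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
        phi += (params.phi_in - params.phi_out) * 0.5 * (
            1.0 + np.tanh((R - dist) / params.ell)
        )
    return np.minimum(phi, params.phi_in)


def bleach_init(
    spec: GeometrySpec, params: ModelParams, style: str = "equilibrium"
) -> np.ndarray:
    """Post-bleach concentration field for the box.

    ``"equilibrium"``: everything outside the bleached spheres keeps its
    equilibrium concentration (``u = 1``), which is what a bleach ROI does
    to a multi-droplet system — unbleached neighbours stay at ``phi_in``.
    ``"dilute"``: the surroundings hold the dilute level ``phi_out``
    everywhere, the sharp-interface idealization used by the radial
    full-bleach runs.
    """
    phi = build_phi_tot_3d(spec, params)
    xs, ys, zs = spec.cell_centers()
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    if style == "equilibrium":
        c = phi.copy()
    elif style == "dilute":
        c = np.full(phi.shape, params.phi_out)
    else:
        raise ValueError(f"unknown bleach init style: {style!r}")
    for (cx, cy, cz), R, bl in zip(spec.centers, spec.radii, spec.bleached):
        if bl:
            dist = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
            c[dist <= R] = 0.0
    return c


def _assemble(phi: np.ndarray, params: ModelParams, h: float):
    """Symmetric 7-point conservative operator S and capacity M (flat)."""
    kappa = diffusivity_of_phi(phi, params) * phi
    nz, ny, nx = phi.shape
    n = phi.size
    diag = np.zeros(n)
    rows, cols, vals = [], [], []
    idx = np.arange(n).reshape(nz, ny, nx)
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        k_lo = kappa[tuple(sl_lo)]
        k_hi = kappa[tuple(sl_hi)]
        # harmonic face conductance times face area / distance = h
        g = (2.0 * k_lo * k_hi / (k_lo + k_hi)) * h
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        g = g.ravel()
        rows.append(i_lo)
        cols.append(i_hi)
        vals.append(g)
        rows.append(i_hi)
        cols.append(i_lo)
        vals.append(g)
        np.add.at(diag, i_lo, -g)
        np.add.at(diag, i_hi, -g)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    S = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    M = phi.ravel() * h**3
    return S, M


def solve_full_model_3d(
    spec: GeometrySpec,
    params: ModelParams,
    init: np.ndarray | None = None,
    times: np.ndarray | None = None,
    n_steps: int = 150,
    cg_tol: float = 1e-10,
) -> CartesianField:
    """Conservative diffuse-interface solve on the box.

    As in the radial solver the state is ``u = c/phi_tot`` with flux
    ``-D(phi) phi grad u``; all outer box faces are no-flux.  ``init`` is
    the initial concentration on the grid; by default every bleached
    droplet starts empty and the rest of the system unbleached
    (``u = 1``).  Mass is conserved to the linear-solver tolerance.
    """
    if times is None:
        raise ValueError("output times are required")
    if spec.spacing > min(spec.radii) / 8 + 1e-12:
        raise ValueError(
            "grid spacing too coarse: need spacing <= R/8 to resolve the droplet"
        )
    times = np.asarray(times, dtype=float)
    phi = build_phi_tot_3d(spec, params)
    h = spec.spacing
    S, M = _assemble(phi, params, h)

    if init is None:
        xs, ys, zs = spec.cell_centers()
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        u0 = np.ones(phi.shape)
        for (cx, cy, cz), R, bl in zip(spec.centers, spec.radii, spec.bleached):
            if bl:
                dist = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
                u0[dist <= R] = 0.0
        u0 = u0.ravel()
    else:
        init = np.asarray(init, dtype=float)
        if init.shape != phi.shape:
            raise ValueError("init must match the grid shape")
        u0 = (init / phi).ravel()

    out = np.empty((times.size, phi.size))
    out[0] = u0
    u = u0.copy()
    span = times[-1] - times[0]
    dt_target = span / max(n_steps, 1) if span > 0 else 0.0
    Minv = 1.0 / M

    def step(u, dt, theta):
        A = sparse.diags(M) - theta * dt * S
        rhs = M * u + (1 - theta) * dt * (S @ u)
        x, info = cg(A, rhs, x0=u, rtol=cg_tol, atol=0.0, M=sparse.diags(Minv))
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
        return x

    first = True
    for k in range(1, times.size):
        t0, t1 = times[k - 1], times[k]
        nsub = max(1, int(np.ceil((t1 - t0) / dt_target))) if dt_target > 0 else 1
        dt = (t1 - t0) / nsub
        for j in range(nsub):
            if first and j == 0:
                for _ in range(2):  # damped start-up
                    u = step(u, dt / 2, 1.0)
            else:
                u = step(u, dt, 0.5)
        first = False
        out[k] = u

    values = (out * phi.ravel()).reshape(times.size, *phi.shape)
    return CartesianField(spec, times, values, phi)


# --------------------------------------------------------------------------
# reductions
# --------------------------------------------------------------------------

def droplet_average_recovery(field: CartesianField, droplet: int = 0) -> np.ndarray:
    """Mean unbleached concentration over one droplet's volume, per frame."""
    (cx, cy, cz) = field.spec.centers[droplet]
    R = field.spec.radii[droplet]
    xs, ys, zs = field.spec.cell_centers()
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    inside = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= R**2
    return field.values[:, inside].mean(axis=1)


def midplane_stack(
    field: CartesianField,
    droplet: int = 0,
    dr: float | None = None,
    n_angles: int = 64,
) -> ProfileStack:
    """Azimuthally averaged mid-plane recovery profiles of one droplet.

    Extracts the horizontal plane through the droplet centre (linear
    interpolation between the two nearest cell layers), samples the
    normalized concentration ``u = c/phi`` on circles of radius ``r``
    (bilinear interpolation, ``n_angles`` equispaced angles) and averages
    over the angle.  Returns the same data product the image pipeline
    produces from a real midplane movie, with the droplet radius attached.
    ``dr`` is the radial sampling step (default: half the grid spacing).
    """
    from scipy.interpolate import RegularGridInterpolator

    (cx, cy, cz) = field.spec.centers[droplet]
    R = field.spec.radii[droplet]
    xs, ys, zs = field.spec.cell_centers()
    kz = np.searchsorted(zs, cz)
    kz = min(max(kz, 1), zs.size - 1)
    w = (cz - zs[kz - 1]) / (zs[kz] - zs[kz - 1])
    u = field.values / field.phi
    plane = (1 - w) * u[:, kz - 1] + w * u[:, kz]  # (nt, ny, nx)

    if dr is None:
        dr = field.spec.spacing / 2
    radii = np.arange(dr / 2, R + 2 * field.spec.spacing, dr)
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    px = cx + radii[:, None] * np.cos(theta)[None, :]
    py = cy + radii[:, None] * np.sin(theta)[None, :]
    pts = np.stack([py.ravel(), px.ravel()], axis=-1)

    profs = np.empty((field.times.size, radii.size))
    for k in range(field.times.size):
        itp = RegularGridInterpolator(
            (ys, xs), plane[k], bounds_error=False, fill_value=None
        )
        profs[k] = itp(pts).reshape(radii.size, theta.size).mean(axis=1)
    return ProfileStack(
        radii=radii,
        times=field.times.copy(),
        intensities=profs,
        bin_counts=np.full(radii.size, n_angles),
        R=R,
    )


def recovery_slowdown_factor(
    curve_env: np.ndarray,
    curve_free: np.ndarray,
    times_env: np.ndarray,
    times_free: np.ndarray | None = None,
) -> float:
    """Ratio of half-recovery times, environment over free space.

    Each curve is normalized to its own span (initial value to plateau);
    t50 is the first crossing of 50%, located by linear interpolation.
    """
    if times_free is None:
        times_free = times_env

    def t50(curve, times):
        curve = np.asarray(curve, dtype=float)
        lo, hi = curve[0], curve[-1]
        if hi <= lo:
            raise ValueError("curve does not recover")
        frac = (curve - lo) / (hi - lo)
        above = np.nonzero(frac >= 0.5)[0]
        if above.size == 0:
            raise ValueError("curve never reaches 50% of its plateau")
        i = above[0]
        if i == 0:
            return float(times[0])
        f0, f1 = frac[i - 1], frac[i]
        return float(times[i - 1] + (0.5 - f0) / (f1 - f0) * (times[i] - times[i - 1]))

    return t50(curve_env, times_env) / t50(curve_free, times_free)
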