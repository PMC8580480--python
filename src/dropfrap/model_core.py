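"""Physical parameters and equilibrium profiles of a phase-separated droplet.

A single liquid condensate of radius ``R`` sits in a dilute phase inside a
closed spherical domain of radius ``L``.  At equilibrium the volume fraction
of condensate material follows a tanh profile of width ``ell`` across the
interface, high inside (``phi_in``) and low outside (``phi_out``).  The ratio
``P = phi_in / phi_out`` is the partition coefficient.  Unbleached molecules
diffuse with coefficient ``D_in`` deep inside the droplet and ``D_out`` deep
outside; across the interface the diffusivity interpolates linearly in the
local volume fraction.

Units are micrometres and seconds throughout; volume fractions and
normalized intensities are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ModelParams",
    "phi_tot_profile",
    "diffusivity_profile",
    "diffusivity_of_phi",
    "partition_coefficient",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of one droplet system.

    Parameters
    ----------
    D_in : float
        Diffusivity inside the droplet (um^2/s).
    D_out : float
        Diffusivity in the dilute phase (um^2/s).
    R : float
        Droplet radius (um).
    ell : float
        Interface width of the tanh profile (um).
    L : float
        Radius of the closed spherical domain (um).
    phi_in : float
        Equilibrium volume fraction inside, in (0, 1).
    phi_out : float
        Equilibrium volume fraction outside, in (0, phi_in].
    """

    D_in: float
    D_out: float
    R: float
    ell: float
    L: float
    phi_in: float
    phi_out: float

    def __post_init__(self) -> None:
        if not (self.D_in > 0 and self.D_out > 0):
            raise ValueError("diffusivities must be positive")
        if not (0 < self.ell < self.R < self.L):
            raise ValueError("require 0 < ell < R < L")
        if not (0 < self.phi_out <= self.phi_in < 1):
            raise ValueError("require 0 < phi_out <= phi_in < 1")
        if self.phi_in == self.phi_out and self.D_in != self.D_out:
            # P = 1 means no phase separation, so the two diffusivities
            # cannot differ.
            raise ValueError("phi_in == phi_out requires D_in == D_out")

    @property
    def P(self) -> float:
        """Partition coefficient phi_in / phi_out."""
        return self.phi_in / self.phi_out

    @classmethod
    def from_p(
        cls,
        D_in: float,
        D_out: float,
        R: float,
        P: float,
        ell: float | None = None,
        L: float | None = None,
        phi_in: float = 0.3,
    ) -> "ModelParams":
        """Build parameters from a partition coefficient.

        Only the ratio ``P`` matters for the dynamics of normalized
        intensities, so ``phi_in`` defaults to a typical dense-phase value.
        ``ell`` defaults to ``R/100`` (thin interface) and ``L`` to ``10 R``.
        """
        if P < 1:
            raise ValueError("partition coefficient must be >= 1")
        if ell is None:
            ell = R / 100.0
        if L is None:
            L = 10.0 * R
        return cls(
            D_in=D_in,
            D_out=D_out,
            R=R,
            ell=ell,
            L=L,
            phi_in=phi_in,
            phi_out=phi_in / P,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(v) for k, v in d.items()})


def _check_r(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("radial coordinates must be finite")
    if np.any(r < 0):
        raise ValueError("radial coordinates must be non-negative")
    return r


def phi_tot_profile(r: np.ndarray, params: ModelParams) -> np.ndarray:
    """Equilibrium volume-fraction profile ``phi_tot(r)``.

    ``phi_out + (phi_in - phi_out) * (1 + tanh((R - r)/ell)) / 2`` —
    a tanh step that decreases from ``phi_in`` at the droplet centre to
    ``phi_out`` far outside, crossing the midpoint at ``r = R``.
    """
    r = _check_r(r)
    h = 0.5 * (1.0 + np.tanh((params.R - r) / params.ell))
    return params.phi_out + (params.phi_in - params.phi_out) * h


def diffusivity_profile(
    r: np.ndarray, params: ModelParams, kind: str = "resistive"
) -> np.ndarray:
    """Position-dependent diffusivity ``D(phi_tot(r))``.

    The mobility inside the interface is not fixed by equilibrium
    thermodynamics, only its endpoints are: ``D = D_in`` deep inside and
    ``D = D_out`` deep outside.  Two interpolants are provided:

    ``"resistive"`` (default)
        The diffusive resistivity ``1/(D phi_tot)`` is linear in the tanh
        weight.  Because the weight profile is antisymmetric about r = R,
        the excess interface resistance integrates to zero and the solution
        converges to the sharp-interface model at first order in ``ell``.

    ``"linear"``
        ``D = D_out + (D_in - D_out) (phi_tot - phi_out)/(phi_in - phi_out)``.
        Simplest choice; carries an O(ell) effective interface resistance
        relative to the sharp-interface model, noticeable at large P.

    The linear kind is monotone in r; for the resistive kind the monotone
    quantity is the mobility ``D * phi_tot`` (the diffusivity itself may dip
    slightly where phi rises faster than the conductance).  For a thin
    interface the fitted dynamics are insensitive to the choice.
    """
    r = _check_r(r)
    return diffusivity_of_phi(phi_tot_profile(r, params), params, kind=kind)


def diffusivity_of_phi(
    phi: np.ndarray, params: ModelParams, kind: str = "resistive"
) -> np.ndarray:
    """Diffusivity as a function of the local total volume fraction.

    See :func:`diffusivity_profile` for the two interpolation kinds.
    """
    phi = np.asarray(phi, dtype=float)
    if params.phi_in == params.phi_out:
        # P = 1: constant diffusivity (validated equal at construction).
        return np.full_like(phi, params.D_in, dtype=float)
    w = (phi - params.phi_out) / (params.phi_in - params.phi_out)
    w = np.clip(w, 0.0, 1.0)
    if kind == "linear":
        return params.D_out + (params.D_in - params.D_out) * w
    if kind == "resistive":
        k_in = params.D_in * params.phi_in
        k_out = params.D_out * params.phi_out
        kappa = 1.0 / ((1.0 - w) / k_out + w / k_in)
        return kappa / phi
    raise ValueError(f"unknown diffusivity interpolation kind: {kind!r}")


def partition_coefficient(params: ModelParams) -> float:
    """Partition coefficient ``P = phi_in / phi_out``."""
    return params.phi_in / params.phi_out
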