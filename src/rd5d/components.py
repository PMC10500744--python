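"""Core containers for discrete relaxation–diffusion distributions.

A voxel's content is modelled as a small set of microscopic environments
("components"), each an axially symmetric diffusion tensor with axial and
radial diffusivities (D∥, D⊥), an orientation (θ, φ), a transverse
relaxation rate R2, and a non-negative signal weight.  A
:class:`DiscreteDistribution` is one such weighted set — one plausible
solution of the inverse problem for one voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["Component", "DiscreteDistribution"]


@dataclass(frozen=True)
class Component:
    """One microscopic environment.

    Parameters
    ----------
    r2 : float
        Transverse relaxation rate, s⁻¹.  Must be positive.
    d_par, d_perp : float
        Axial and radial diffusivities of the axially symmetric diffusion
        tensor, m²·s⁻¹.  Must be positive.
    theta, phi : float
        Polar and azimuthal angles of the tensor symmetry axis, radians.
    weight : float
        Non-negative signal amplitude (arbitrary units).
    """

    r2: float
    d_par: float
    d_perp: float
    theta: float = 0.0
    phi: float = 0.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.r2 <= 0:
            raise ValueError(f"r2 must be positive, got {self.r2}")
        if self.d_par <= 0 or self.d_perp <= 0:
            raise ValueError("diffusivities must be positive, got "
                             f"d_par={self.d_par}, d_perp={self.d_perp}")
        if self.weight < 0:
            raise ValueError(f"weight must be non-negative, got {self.weight}")
        if not 0 <= self.theta <= np.pi:
            raise ValueError(f"theta must lie in [0, pi], got {self.theta}")


@dataclass
class DiscreteDistribution:
    """A weighted set of components — one voxel solution.

    Stored as parallel arrays for vectorised kernel evaluation.  The sum of
    weights plays the role of the fitted unattenuated amplitude S0.  An empty
    distribution (zero components) is the "trivial solution" a stochastic
    inversion may return for uninformative data.
    """

    r2: np.ndarray
    d_par: np.ndarray
    d_perp: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    weights: np.ndarray
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        arrs = [np.atleast_1d(np.asarray(a, dtype=float)) for a in
                (self.r2, self.d_par, self.d_perp, self.theta, self.phi,
                 self.weights)]
        n = arrs[0].shape[0]
        if any(a.shape != (n,) for a in arrs):
            raise ValueError("all component arrays must share one length")
        (self.r2, self.d_par, self.d_perp,
         self.theta, self.phi, self.weights) = arrs
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    # -- construction ------------------------------------------------------

    @classmethod
    def empty(cls) -> "DiscreteDistribution":
        z = np.empty(0)
        return cls(z, z, z, z, z, z)

    @classmethod
    def from_components(cls, comps: Sequence[Component]) -> "DiscreteDistribution":
        if not comps:
            return cls.empty()
        return cls(
            r2=np.array([c.r2 for c in comps]),
            d_par=np.array([c.d_par for c in comps]),
            d_perp=np.array([c.d_perp for c in comps]),
            theta=np.array([c.theta for c in comps]),
            phi=np.array([c.phi for c in comps]),
            weights=np.array([c.weight for c in comps]),
        )

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return self.r2.shape[0]

    def __iter__(self) -> Iterator[Component]:
        for i in range(len(self)):
            yield Component(self.r2[i], self.d_par[i], self.d_perp[i],
                            self.theta[i], self.phi[i], self.weights[i])

    @property
    def s0(self) -> float:
        """Total weight — the implied unattenuated signal amplitude."""
        return float(self.weights.sum())

    def with_weights(self, weights: np.ndarray) -> "DiscreteDistribution":
        return DiscreteDistribution(self.r2, self.d_par, self.d_perp,
                                    self.theta, self.phi, weights)

    def select(self, idx) -> "DiscreteDistribution":
        return DiscreteDistribution(self.r2[idx], self.d_par[idx],
                                    self.d_perp[idx], self.theta[idx],
                                    self.phi[idx], self.weights[idx])

    def concat(self, other: "DiscreteDistribution") -> "DiscreteDistribution":
        return DiscreteDistribution(
            *(np.concatenate([a, b]) for a, b in zip(
                (self.r2, self.d_par, self.d_perp, self.theta, self.phi,
                 self.weights),
                (other.r2, other.d_par, other.d_perp, other.theta, other.phi,
                 other.weights))))
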