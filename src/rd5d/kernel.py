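"""Forward signal model for joint relaxation–diffusion encoding.

The measured signal of one microscopic environment at one acquisition point
(τE, b, bΔ, Θ, Φ) is

    K = exp(−τE·R2) · exp(−b·Diso·[1 + 2·bΔ·DΔ·P2(cos β)])

with isotropic diffusivity Diso = (D∥ + 2 D⊥)/3, normalized diffusion
anisotropy DΔ = (D∥ − D⊥)/(3 Diso), P2 the second Legendre polynomial, and
β the arc angle between the symmetry axes of the encoding b-tensor and of
the diffusion tensor.  A voxel signal is the weight-sum of K over its
components (Laplace-type multi-exponential superposition).

All quantities are SI: b in s·m⁻² (10⁹ s·m⁻² = 1 ms·µm⁻²), diffusivities in
m²·s⁻¹, τE in s, R2 in s⁻¹.  Attenuations are assembled in log space and
exponentiated once, so large b·Diso products underflow gracefully to 0.
"""

from __future__ import annotations

import numpy as np

from .components import Component, DiscreteDistribution

__all__ = [
    "iso_delta_from_eigs", "eigs_from_iso_delta", "legendre_p2", "cos_beta",
    "kernel_value", "kernel_matrix", "synthesize_signal",
]


def iso_delta_from_eigs(d_par, d_perp):
    """Map eigenvalues (D∥, D⊥) to (Diso, DΔ).

    Diso = (D∥ + 2 D⊥)/3 is the orientation-invariant mean diffusivity;
    DΔ ∈ [−0.5, 1] measures tensor shape (−0.5 planar, 0 sphere, 1 stick).

    Returns
    -------
    (d_iso, d_delta) : floats or ndarrays matching the input shape.
    """
    d_par = np.asarray(d_par, dtype=float)
    d_perp = np.asarray(d_perp, dtype=float)
    if np.any(d_par <= 0) or np.any(d_perp <= 0):
        raise ValueError("diffusivities must be positive")
    d_iso = (d_par + 2.0 * d_perp) / 3.0
    d_delta = (d_par - d_perp) / (3.0 * d_iso)
    if d_iso.ndim == 0:
        return float(d_iso), float(d_delta)
    return d_iso, d_delta


def eigs_from_iso_delta(d_iso, d_delta):
    """Inverse of :func:`iso_delta_from_eigs`: D∥ = Diso(1+2DΔ), D⊥ = Diso(1−DΔ)."""
    d_iso = np.asarray(d_iso, dtype=float)
    d_delta = np.asarray(d_delta, dtype=float)
    if np.any(d_iso <= 0):
        raise ValueError("d_iso must be positive")
    if np.any(d_delta < -0.5) or np.any(d_delta > 1.0):
        raise ValueError("d_delta must lie in [-0.5, 1]")
    d_par = d_iso * (1.0 + 2.0 * d_delta)
    d_perp = d_iso * (1.0 - d_delta)
    if d_par.ndim == 0:
        return float(d_par), float(d_perp)
    return d_par, d_perp


def legendre_p2(x):
    """Second Legendre polynomial P2(x) = (3x² − 1)/2 on [−1, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("legendre_p2 argument must lie in [-1, 1]")
    out = 0.5 * (3.0 * x * x - 1.0)
    return float(out) if out.ndim == 0 else out


def cos_beta(Theta, Phi, theta, phi):
    """Cosine of the arc angle between two axes given in spherical angles.

    cos β = cos Θ cos θ + cos(Φ − φ) sin Θ sin θ — the dot product of the
    two unit vectors.
    """
    out = (np.cos(Theta) * np.cos(theta)
           + np.cos(np.asarray(Phi) - np.asarray(phi))
           * np.sin(Theta) * np.sin(theta))
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def _log_attenuation(tau_e, b, b_delta, Theta, Phi, dist: DiscreteDistribution):
    """Log-attenuation matrix, shape (n_points, n_components)."""
    d_iso, d_delta = iso_delta_from_eigs(dist.d_par, dist.d_perp)
    d_iso = np.atleast_1d(d_iso)
    d_delta = np.atleast_1d(d_delta)
    cb = cos_beta(Theta[:, None], Phi[:, None],
                  dist.theta[None, :], dist.phi[None, :])
    # clamp rounding excursions past |cos β| = 1 before P2
    cb = np.clip(cb, -1.0, 1.0)
    p2 = 0.5 * (3.0 * cb * cb - 1.0)
    diff = b[:, None] * d_iso[None, :] * (
        1.0 + 2.0 * b_delta[:, None] * d_delta[None, :] * p2)
    relax = tau_e[:, None] * dist.r2[None, :]
    return -(relax + diff)


def kernel_value(point, comp: Component) -> float:
    """Signal attenuation of one component at one acquisition point.

    ``point`` is anything with attributes tau_e, b, b_delta, Theta, Phi.
    Lies in (0, 1] for valid inputs; equals 1 only as τE, b → 0.
    """
    dist = DiscreteDistribution.from_components([comp])
    la = _log_attenuation(np.array([point.tau_e]), np.array([point.b]),
                          np.array([point.b_delta]), np.array([point.Theta]),
                          np.array([point.Phi]), dist)
    return float(np.exp(la[0, 0]))


def kernel_matrix(scheme, dist) -> np.ndarray:
    """Attenuation matrix K with K[i, j] = kernel of component j at point i.

    ``scheme`` is an :class:`~rd5d.scheme.AcquisitionScheme`; ``dist`` a
    :class:`DiscreteDistribution` or sequence of :class:`Component`.
    """
    if not isinstance(dist, DiscreteDistribution):
        dist = DiscreteDistribution.from_components(list(dist))
    if len(scheme) == 0 or len(dist) == 0:
        raise ValueError("kernel_matrix needs a non-empty scheme and "
                         "component list")
    return np.exp(_log_attenuation(scheme.tau_e, scheme.b, scheme.b_delta,
                                   scheme.Theta, scheme.Phi, dist))


def synthesize_signal(scheme, dist: DiscreteDistribution) -> np.ndarray:
    """Forward-model signal: Σ_j w_j · K(point_i, component_j) per point i.

    Linear in the weights; an empty distribution gives an all-zero signal.
    """
    if len(dist) == 0:
        return np.zeros(len(scheme))
    return kernel_matrix(scheme, dist) @ dist.weights
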