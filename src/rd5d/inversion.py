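"""Nonparametric Monte Carlo inversion of relaxation–diffusion signals.

The per-voxel inverse problem — recover a distribution P(R2, D) from a few
hundred encoded measurements — is a severely ill-posed Laplace-type
inversion.  Instead of a regularized fit on a fixed grid, the solution
space is explored stochastically:

1. draw ``n_seed`` candidate components log-uniformly from a sampling box,
   fit their weights by non-negative least squares (NNLS), keep the
   nonzero-weight survivors;
2. repeat ``n_merge_rounds`` times, each round merging the survivors with a
   fresh random draw before refitting (residual never increases — the
   dictionary is a superset);
3. polish for ``n_mutation_rounds`` rounds: duplicate the surviving
   components, jitter the copies slightly in log-parameter and angle space,
   refit original ∪ mutated, keep the lowest-residual configuration;
4. finalize by keeping the ``n_final`` highest-weight components and
   refitting.

Repeating the whole procedure ``n_ensemble`` times (optionally on
bootstrap-resampled measurement rows) yields an ensemble of plausible
solutions whose spread quantifies the inversion uncertainty.

:class:`MonteCarloInverter` wraps the procedure as a scikit-learn style
estimator over arrays of voxel signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import nnls as _scipy_nnls
from sklearn.base import BaseEstimator

from .components import DiscreteDistribution
from .kernel import iso_delta_from_eigs, kernel_matrix

__all__ = [
    "SamplingBox", "InversionConfig", "SolutionEnsemble",
    "seed_components", "nnls_fit", "prune_nonzero", "merge_and_refit",
    "mutate", "invert_voxel", "bootstrap_ensemble", "repair_voxel",
    "to_iso_delta", "MonteCarloInverter",
]


@dataclass(frozen=True)
class SamplingBox:
    """Axis-aligned candidate-component box (log10 / angular coordinates).

    Defaults: 1 < R2 < 10^1.5 ≈ 31.6 s⁻¹, 10⁻¹⁰ < D∥, D⊥ < 10⁻⁸·⁵ m²·s⁻¹,
    cos θ ∈ (0, 1) (upper hemisphere; sign is immaterial for axially
    symmetric tensors), φ ∈ (0, 2π).
    """

    log10_r2: tuple[float, float] = (0.0, 1.5)
    log10_d_par: tuple[float, float] = (-10.0, -8.5)
    log10_d_perp: tuple[float, float] = (-10.0, -8.5)
    cos_theta: tuple[float, float] = (0.0, 1.0)
    phi: tuple[float, float] = (0.0, 2.0 * np.pi)

    def __post_init__(self) -> None:
        for name in ("log10_r2", "log10_d_par", "log10_d_perp",
                     "cos_theta", "phi"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper")

    def contains(self, dist: DiscreteDistribution, atol: float = 1e-9) -> bool:
        checks = [
            (np.log10(dist.r2), self.log10_r2),
            (np.log10(dist.d_par), self.log10_d_par),
            (np.log10(dist.d_perp), self.log10_d_perp),
            (np.cos(dist.theta), self.cos_theta),
            (dist.phi, self.phi),
        ]
        return all(np.all(v >= lo - atol) and np.all(v <= hi + atol)
                   for v, (lo, hi) in checks)


@dataclass(frozen=True)
class InversionConfig:
    """Tunables of the Monte Carlo inversion (defaults follow the method)."""

    n_seed: int = 200
    n_merge_rounds: int = 20
    n_mutation_rounds: int = 20
    n_final: int = 10
    n_ensemble: int = 96
    mutation_sigma: float = 0.05       # decades, on log10 R2 / D∥ / D⊥
    mutation_angle: float = np.deg2rad(5.0)
    bootstrap: bool = True             # resample rows per ensemble member
    box: SamplingBox = field(default_factory=SamplingBox)

    def __post_init__(self) -> None:
        for name in ("n_seed", "n_merge_rounds", "n_mutation_rounds",
                     "n_final", "n_ensemble"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mutation_sigma <= 0:
            raise ValueError("mutation_sigma must be positive")


@dataclass
class SolutionEnsemble:
    """N plausible solutions for one voxel, with their squared residuals."""

    solutions: list[DiscreteDistribution]
    residual_ssr: np.ndarray
    repaired: bool = False

    def __post_init__(self) -> None:
        self.residual_ssr = np.asarray(self.residual_ssr, dtype=float)
        if len(self.solutions) != self.residual_ssr.shape[0]:
            raise ValueError("one residual per solution required")
        if np.any(self.residual_ssr < 0):
            raise ValueError("residuals must be non-negative")

    def __len__(self) -> int:
        return len(self.solutions)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def seed_components(box: SamplingBox, n: int,
                    rng: np.random.Generator) -> DiscreteDistribution:
    """Draw n candidates uniformly per box axis (log-uniform in R2, D∥, D⊥;
    uniform in cos θ and φ).  Weights start at zero."""
    if n < 1:
        raise ValueError("n must be >= 1")
    r2 = 10.0 ** rng.uniform(*box.log10_r2, n)
    d_par = 10.0 ** rng.uniform(*box.log10_d_par, n)
    d_perp = 10.0 ** rng.uniform(*box.log10_d_perp, n)
    theta = np.arccos(rng.uniform(*box.cos_theta, n))
    phi = rng.uniform(*box.phi, n)
    return DiscreteDistribution(r2, d_par, d_perp, theta, phi, np.zeros(n))


def nnls_fit(scheme, dist: DiscreteDistribution,
             signal: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares over the component dictionary.

    Returns the weight vector minimising ‖K·w − s‖² s.t. w ≥ 0 and the
    attained sum of squared residuals.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (len(scheme),):
        raise ValueError(f"signal length {signal.shape} does not match the "
                         f"scheme's {len(scheme)} points")
    if len(dist) == 0:
        return np.zeros(0), float(signal @ signal)
    K = kernel_matrix(scheme, dist)
    w, rnorm = _scipy_nnls(K, signal)
    return w, float(rnorm ** 2)


def prune_nonzero(dist: DiscreteDistribution,
                  weights: np.ndarray) -> DiscreteDistribution:
    """Keep components whose fitted weight is strictly positive (the
    active-set solver returns exact zeros for inactive columns)."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != len(dist):
        raise ValueError("weights length must match component count")
    keep = weights > 0
    return dist.select(keep).with_weights(weights[keep])


def merge_and_refit(current: DiscreteDistribution, box: SamplingBox,
                    scheme, signal: np.ndarray, rng: np.random.Generator,
                    n_seed: int = 200) -> tuple[DiscreteDistribution, float]:
    """One exploration round: merge survivors with a fresh random draw,
    refit, prune.  The merged dictionary contains the current one, so the
    residual cannot increase."""
    fresh = seed_components(box, n_seed, rng)
    merged = current.concat(fresh) if len(current) else fresh
    w, ssr = nnls_fit(scheme, merged, signal)
    return prune_nonzero(merged, w), ssr


def mutate(dist: DiscreteDistribution, mutation_sigma: float,
           mutation_angle: float, rng: np.random.Generator,
           box: SamplingBox) -> DiscreteDistribution:
    """Jittered copies of each component: log-normal multiplicative noise on
    R2 / D∥ / D⊥ (scale in decades) and Gaussian angular jitter, clipped to
    the box."""
    n = len(dist)
    if n == 0:
        return DiscreteDistribution.empty()
    log_r2 = np.log10(dist.r2) + rng.normal(0, mutation_sigma, n)
    log_dpar = np.log10(dist.d_par) + rng.normal(0, mutation_sigma, n)
    log_dperp = np.log10(dist.d_perp) + rng.normal(0, mutation_sigma, n)
    cos_th = np.cos(dist.theta + rng.normal(0, mutation_angle, n))
    phi = dist.phi + rng.normal(0, mutation_angle, n)
    eps = 1e-12
    return DiscreteDistribution(
        10.0 ** np.clip(log_r2, *box.log10_r2),
        10.0 ** np.clip(log_dpar, *box.log10_d_par),
        10.0 ** np.clip(log_dperp, *box.log10_d_perp),
        np.arccos(np.clip(cos_th, box.cos_theta[0],
                          box.cos_theta[1] - eps)),
        np.clip(np.mod(phi, 2 * np.pi), box.phi[0], box.phi[1]),
        np.zeros(n))


def _finalize(dist: DiscreteDistribution, n_final: int, scheme,
              signal: np.ndarray) -> tuple[DiscreteDistribution, float]:
    """Keep the n_final highest-weight components (stable order on ties),
    refit, prune."""
    if len(dist) > n_final:
        order = np.argsort(-dist.weights, kind="stable")[:n_final]
        dist = dist.select(np.sort(order))
    w, ssr = nnls_fit(scheme, dist, signal)
    return prune_nonzero(dist, w), ssr


def invert_voxel(signal: np.ndarray, scheme,
                 config: InversionConfig | None = None,
                 rng: np.random.Generator | int | None = None,
                 return_trace: bool = False):
    """One full Monte Carlo inversion of a single voxel signal.

    Returns the final pruned distribution (≤ ``n_final`` components) and
    its squared residual; with ``return_trace`` additionally the accepted
    ssr after every merge and mutation round (non-increasing by
    construction).
    """
    config = config or InversionConfig()
    rng = np.random.default_rng(rng)
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    current = DiscreteDistribution.empty()
    ssr = float(signal @ signal)
    trace = []
    for _ in range(config.n_merge_rounds):
        current, ssr = merge_and_refit(current, config.box, scheme, signal,
                                       rng, config.n_seed)
        trace.append(ssr)
    for _ in range(config.n_mutation_rounds):
        if len(current) == 0:
            break
        mutated = mutate(current, config.mutation_sigma,
                         config.mutation_angle, rng, config.box)
        trial = current.concat(mutated)
        w, trial_ssr = nnls_fit(scheme, trial, signal)
        if trial_ssr <= ssr:
            current, ssr = prune_nonzero(trial, w), trial_ssr
        trace.append(ssr)
    final = _finalize(current, config.n_final, scheme, signal)
    if return_trace:
        return final[0], final[1], trace
    return final


def _member_rng(seed, voxel_index: int, member_index: int):
    base = 0 if seed is None else int(seed)
    return np.random.default_rng([base, int(voxel_index), int(member_index)])


def bootstrap_ensemble(signal: np.ndarray, scheme,
                       config: InversionConfig | None = None,
                       seed: int | None = None,
                       voxel_index: int = 0) -> SolutionEnsemble:
    """Ensemble of ``n_ensemble`` independent inversions of one voxel.

    Each member runs with its own RNG stream derived from
    (seed, voxel_index, member); when ``config.bootstrap`` is on, each
    member additionally sees a with-replacement resample of the measurement
    rows, otherwise members differ only in their random exploration.
    """
    config = config or InversionConfig()
    signal = np.asarray(signal, dtype=float)
    sols, ssrs = [], []
    for m in range(config.n_ensemble):
        rng = _member_rng(seed, voxel_index, m)
        if config.bootstrap:
            rows = rng.integers(0, len(scheme), size=len(scheme))
            sch, sig = scheme.select(rows), signal[rows]
        else:
            sch, sig = scheme, signal
        dist, _ = invert_voxel(sig, sch, config, rng)
        # residual reported against the unresampled data
        if len(dist):
            pred = kernel_matrix(scheme, dist) @ dist.weights
            ssr = float(np.sum((signal - pred) ** 2))
        else:
            ssr = float(signal @ signal)
        sols.append(dist)
        ssrs.append(ssr)
    return SolutionEnsemble(sols, np.array(ssrs))


def repair_voxel(own: DiscreteDistribution,
                 neighbor_solutions: Sequence[DiscreteDistribution],
                 scheme, signal: np.ndarray,
                 n_final: int = 10) -> DiscreteDistribution | None:
    """Neighbor repair for voxels left with a trivial (empty) solution.

    Pools the voxel's own components with those of its (up to six) spatial
    neighbors, NNLS-fits the pooled set (≤ 7×10 candidates) to this voxel's
    signal, keeps the ``n_final`` highest-weight components and refits.
    Returns ``None`` (unrecoverable marker) if the pool is empty.
    """
    pool = own
    for nb in neighbor_solutions:
        pool = pool.concat(nb)
    if len(pool) == 0:
        return None
    w, _ = nnls_fit(scheme, pool, signal)
    pool = prune_nonzero(pool, w)
    if len(pool) == 0:
        return None
    dist, _ = _finalize(pool, n_final, scheme, np.asarray(signal, float))
    return dist


def to_iso_delta(dist: DiscreteDistribution) -> dict[str, np.ndarray]:
    """Map a distribution to (R2, Diso, DΔ, θ, φ) coordinates.

    Weights are carried over unchanged; returns a dict of arrays.
    """
    if len(dist) == 0:
        return {k: np.empty(0) for k in
                ("r2", "d_iso", "d_delta", "theta", "phi", "weights")}
    d_iso, d_delta = iso_delta_from_eigs(dist.d_par, dist.d_perp)
    return {"r2": dist.r2.copy(), "d_iso": np.atleast_1d(d_iso),
            "d_delta": np.atleast_1d(d_delta), "theta": dist.theta.copy(),
            "phi": dist.phi.copy(), "weights": dist.weights.copy()}


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class MonteCarloInverter(BaseEstimator):
    """Scikit-learn style wrapper: fit voxel signals to solution ensembles.

    Parameters mirror :class:`InversionConfig`.  ``fit`` takes an array of
    shape (n_voxels, n_measurements) whose columns follow ``scheme``; after
    fitting, ``ensembles_`` holds one :class:`SolutionEnsemble` per voxel.
    Voxels are independent work units: results are identical regardless of
    execution order or ``n_jobs`` (per-voxel RNG streams are derived from
    (random_state, voxel index, member index)).

    Examples
    --------
    >>> from rd5d import preset_scheme, MonteCarloInverter
    >>> scheme = preset_scheme("mini")
    >>> inv = MonteCarloInverter(scheme, n_ensemble=4, random_state=0)
    """

    def __init__(self, scheme, n_seed: int = 200, n_merge_rounds: int = 20,
                 n_mutation_rounds: int = 20, n_final: int = 10,
                 n_ensemble: int = 96, mutation_sigma: float = 0.05,
                 mutation_angle: float = np.deg2rad(5.0),
                 bootstrap: bool = True, box: SamplingBox | None = None,
                 random_state: int | None = None, n_jobs: int = 1):
        self.scheme = scheme
        self.n_seed = n_seed
        self.n_merge_rounds = n_merge_rounds
        self.n_mutation_rounds = n_mutation_rounds
        self.n_final = n_final
        self.n_ensemble = n_ensemble
        self.mutation_sigma = mutation_sigma
        self.mutation_angle = mutation_angle
        self.bootstrap = bootstrap
        self.box = box
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _config(self) -> InversionConfig:
        return InversionConfig(
            n_seed=self.n_seed, n_merge_rounds=self.n_merge_rounds,
            n_mutation_rounds=self.n_mutation_rounds, n_final=self.n_final,
            n_ensemble=self.n_ensemble, mutation_sigma=self.mutation_sigma,
            mutation_angle=self.mutation_angle, bootstrap=self.bootstrap,
            box=self.box if self.box is not None else SamplingBox())

    def fit(self, X, y=None):
        """Invert every row of X (n_voxels, n_measurements)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.scheme):
            raise ValueError(f"X has {X.shape[1]} measurements but the "
                             f"scheme has {len(self.scheme)} points")
        cfg = self._config()
        work = (delayed(bootstrap_ensemble)(X[v], self.scheme, cfg,
                                            self.random_state, v)
                for v in range(X.shape[0]))
        self.ensembles_ = list(Parallel(n_jobs=self.n_jobs)(work))
        self.n_features_in_ = X.shape[1]
        return self

    def repair(self, X, neighbors: Sequence[Sequence[int]]):
        """Neighbor-repair voxels whose median solution is trivial.

        ``neighbors[v]`` lists the indices (≤6) adjacent to voxel v.  Uses
        each voxel's lowest-residual member as its candidate pool entry.
        """
        if not hasattr(self, "ensembles_"):
            raise RuntimeError("fit before repair")
        X = np.asarray(X, dtype=float)
        best = [ens.solutions[int(np.argmin(ens.residual_ssr))]
                for ens in self.ensembles_]
        for v, ens in enumerate(self.ensembles_):
            if len(best[v]) > 0:
                continue
            fixed = repair_voxel(best[v], [best[u] for u in neighbors[v]],
                                 self.scheme, X[v], self.n_final)
            if fixed is not None:
                _, ssr = nnls_fit(self.scheme, fixed, X[v])
                self.ensembles_[v] = SolutionEnsemble(
                    [fixed] * len(ens), np.full(len(ens), ssr),
                    repaired=True)
        return self
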