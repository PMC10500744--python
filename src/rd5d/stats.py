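"""Ensemble statistics, distribution-space binning, and voxel summaries.

Every solution in a voxel's ensemble is first reduced to scalar statistics
— weighted means, variances and covariances of {R2, Diso, DΔ²} over its
components — and the per-member statistics are then condensed to a central
value ⟨x⟩ (ensemble median) and an uncertainty σ[x] (median absolute
deviation).  Anisotropy enters as DΔ² because prolate and oblate tensors of
equal |DΔ| are nearly indistinguishable in the data.

Bins are axis-aligned boxes in (log Diso, log D∥/D⊥, log R2) space that
loosely capture the main brain constituents: "big" (fast-diffusing, CSF),
"thin" (elongated tensors, white matter), "thick" (compact tensors, gray
matter).  The thick bin is further split along R2 into low/medium/high
sub-bins.  Bin intervals are half-open [lower, upper) so that binning plus
sub-binning is a deterministic partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .components import Component, DiscreteDistribution
from .inversion import SolutionEnsemble
from .kernel import iso_delta_from_eigs

__all__ = [
    "BinDefinition", "MomentSet", "BinSummary", "VoxelSummary",
    "DEFAULT_BINS", "THICK_SUB_BINS",
    "distribution_moments", "ensemble_reduce", "assign_bin", "bin_fractions",
    "bin_mean_tensor", "component_color", "sub_bin_thick",
    "summarize_ensemble", "mixed_voxel_r2_separation", "collate_summaries",
    "EnsembleSummarizer",
]

_AXES = ("r2", "d_iso", "d_delta2")
_PAIRS = (("r2", "d_iso"), ("r2", "d_delta2"), ("d_iso", "d_delta2"))


@dataclass(frozen=True)
class BinDefinition:
    """Axis-aligned box in (log₁₀ Diso, log₁₀ D∥/D⊥, log₁₀ R2) space."""

    name: str
    log10_d_iso: tuple[float, float]
    log10_ratio: tuple[float, float]
    log10_r2: tuple[float, float]

    def __post_init__(self) -> None:
        for ax in ("log10_d_iso", "log10_ratio", "log10_r2"):
            lo, hi = getattr(self, ax)
            if not lo < hi:
                raise ValueError(f"{self.name}.{ax}: lower must be < upper")


#: Default bins: Diso in m²·s⁻¹ (2–10 ×10⁻⁹ big, 0.1–2 ×10⁻⁹ thin/thick),
#: shape ratio D∥/D⊥ above/below 4 separating thin from thick, and a common
#: R2 range 0.316–100 s⁻¹.
DEFAULT_BINS: tuple[BinDefinition, ...] = (
    BinDefinition("big", (-8.7, -8.0), (-3.5, 3.5), (-0.5, 2.0)),
    BinDefinition("thin", (-10.0, -8.7), (0.6, 3.5), (-0.5, 2.0)),
    BinDefinition("thick", (-10.0, -8.7), (-3.5, 0.6), (-0.5, 2.0)),
)

#: R2 sub-ranges splitting the thick bin (log₁₀ s⁻¹): low = T2 of 63 ms–3.16 s,
#: medium = 40–63 ms, high = 10–40 ms.
THICK_SUB_BINS: Mapping[str, tuple[float, float]] = {
    "low": (-0.5, 1.2), "medium": (1.2, 1.4), "high": (1.4, 2.0),
}


@dataclass
class MomentSet:
    """Weighted means/variances/covariances of {R2, Diso, DΔ²} in one
    solution."""

    e: dict[str, float]
    var: dict[str, float]
    cov: dict[tuple[str, str], float]


@dataclass
class BinSummary:
    fraction: float
    moments: dict[str, float]          # medians of per-member bin moments
    uncertainty: dict[str, float]      # MADs of the same
    mean_tensor: np.ndarray | None     # 3×3 lab-frame tensor (median)
    rgb: np.ndarray | None


@dataclass
class VoxelSummary:
    """Per-voxel scalar statistics condensed from a solution ensemble."""

    s0_med: float
    stats: dict[str, float]            # ⟨x⟩ per statistic name
    uncertainty: dict[str, float]      # σ[x] per statistic name
    bins: dict[str, BinSummary] = field(default_factory=dict)
    sub_bins: dict[str, float] = field(default_factory=dict)
    n_defined: int = 0                 # members with defined moments


# ---------------------------------------------------------------------------
# per-solution statistics
# ---------------------------------------------------------------------------

def _axis_values(dist: DiscreteDistribution) -> dict[str, np.ndarray]:
    d_iso, d_delta = iso_delta_from_eigs(dist.d_par, dist.d_perp)
    return {"r2": dist.r2, "d_iso": np.atleast_1d(d_iso),
            "d_delta2": np.atleast_1d(d_delta) ** 2}


def distribution_moments(dist: DiscreteDistribution) -> MomentSet | None:
    """Weight-normalized E/Var/Cov over {R2, Diso, DΔ²}; ``None`` when the
    distribution is empty or carries zero total weight."""
    if len(dist) == 0 or dist.weights.sum() <= 0:
        return None
    f = dist.weights / dist.weights.sum()
    x = _axis_values(dist)
    e = {k: float(f @ v) for k, v in x.items()}
    var = {k: float(f @ (v - e[k]) ** 2) for k, v in x.items()}
    cov = {(a, b): float(f @ ((x[a] - e[a]) * (x[b] - e[b])))
           for a, b in _PAIRS}
    return MomentSet(e, var, cov)


def ensemble_reduce(values: Sequence[float]) -> tuple[float, float]:
    """(median, median absolute deviation) over finite entries; an
    all-undefined list propagates as (nan, nan)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return float("nan"), float("nan")
    med = float(np.median(arr))
    return med, float(np.median(np.abs(arr - med)))


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _bin_index(dist: DiscreteDistribution,
               bins: Sequence[BinDefinition]) -> np.ndarray:
    """Index of the first matching bin per component; −1 when outside all."""
    x = _axis_values(dist)
    log_iso = np.log10(x["d_iso"])
    log_ratio = np.log10(dist.d_par / dist.d_perp)
    log_r2 = np.log10(dist.r2)
    out = np.full(len(dist), -1, dtype=int)
    for k, bd in enumerate(bins):
        hit = ((log_iso >= bd.log10_d_iso[0]) & (log_iso < bd.log10_d_iso[1])
               & (log_ratio >= bd.log10_ratio[0])
               & (log_ratio < bd.log10_ratio[1])
               & (log_r2 >= bd.log10_r2[0]) & (log_r2 < bd.log10_r2[1]))
        out[(out == -1) & hit] = k
    return out


def assign_bin(comp: Component,
               bins: Sequence[BinDefinition] = DEFAULT_BINS) -> str | None:
    """Name of the first bin containing the component, or ``None``."""
    idx = _bin_index(DiscreteDistribution.from_components([comp]), bins)[0]
    return None if idx < 0 else bins[idx].name


def bin_fractions(dist: DiscreteDistribution,
                  bins: Sequence[BinDefinition] = DEFAULT_BINS,
                  ) -> dict[str, float]:
    """Signal-weight fraction per bin (relative to the voxel's total)."""
    total = dist.weights.sum()
    if total <= 0:
        raise ValueError("bin fractions undefined for zero total weight")
    idx = _bin_index(dist, bins)
    return {bd.name: float(dist.weights[idx == k].sum() / total)
            for k, bd in enumerate(bins)}


def _rotation(theta: float, phi: float) -> np.ndarray:
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    return np.array([[cp * ct, -sp, cp * st],
                     [sp * ct, cp, sp * st],
                     [-st, 0.0, ct]])


def _lab_tensor(dist: DiscreteDistribution) -> np.ndarray:
    """Weight-averaged lab-frame diffusion tensor of a component set."""
    f = dist.weights / dist.weights.sum()
    out = np.zeros((3, 3))
    for i in range(len(dist)):
        R = _rotation(dist.theta[i], dist.phi[i])
        out += f[i] * R @ np.diag([dist.d_perp[i], dist.d_perp[i],
                                   dist.d_par[i]]) @ R.T
    return out


def bin_mean_tensor(dist: DiscreteDistribution, bin_def: BinDefinition,
                    bins: Sequence[BinDefinition] = DEFAULT_BINS,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Lab-frame mean tensor of a bin's components and its direction-encoded
    color [R,G,B] = [Dxx, Dyy, Dzz]/max(Dxx, Dyy, Dzz)."""
    idx = _bin_index(dist, bins)
    k = [b.name for b in bins].index(bin_def.name)
    sub = dist.select(idx == k)
    if len(sub) == 0 or sub.weights.sum() <= 0:
        raise ValueError(f"bin {bin_def.name!r} holds no weight")
    D = _lab_tensor(sub)
    diag = np.diag(D)
    return D, diag / diag.max()


def component_color(comp: Component) -> np.ndarray:
    """Direction-encoded color of one component:
    |[cos φ sin θ, sin φ sin θ, cos θ]| · |D∥−D⊥|/max(D∥, D⊥);
    isotropic components map to black."""
    axis = np.array([np.cos(comp.phi) * np.sin(comp.theta),
                     np.sin(comp.phi) * np.sin(comp.theta),
                     np.cos(comp.theta)])
    scale = abs(comp.d_par - comp.d_perp) / max(comp.d_par, comp.d_perp)
    return np.abs(axis) * scale


def sub_bin_thick(dist: DiscreteDistribution,
                  bins: Sequence[BinDefinition] = DEFAULT_BINS,
                  sub_bins: Mapping[str, tuple[float, float]] = THICK_SUB_BINS,
                  ) -> dict[str, float]:
    """Split the thick-bin weight along log R2; fractions are relative to
    the voxel's total weight, so they sum to the thick-bin fraction."""
    total = dist.weights.sum()
    if total <= 0:
        raise ValueError("sub-bin fractions undefined for zero total weight")
    idx = _bin_index(dist, bins)
    k = [b.name for b in bins].index("thick")
    sub = dist.select(idx == k)
    log_r2 = np.log10(sub.r2) if len(sub) else np.empty(0)
    out = {}
    for name, (lo, hi) in sub_bins.items():
        m = (log_r2 >= lo) & (log_r2 < hi)
        out[name] = float(sub.weights[m].sum() / total) if len(sub) else 0.0
    return out


# ---------------------------------------------------------------------------
# ensemble → voxel summary
# ---------------------------------------------------------------------------

def _moment_record(ms: MomentSet) -> dict[str, float]:
    rec = {f"e_{k}": ms.e[k] for k in _AXES}
    rec.update({f"var_{k}": ms.var[k] for k in _AXES})
    rec.update({f"cov_{a}_{b}": ms.cov[(a, b)] for a, b in _PAIRS})
    return rec


def summarize_ensemble(ensemble: SolutionEnsemble,
                       bins: Sequence[BinDefinition] = DEFAULT_BINS,
                       ) -> VoxelSummary:
    """Condense one voxel's ensemble to median/MAD statistics.

    Statistics are computed per ensemble member and then reduced — never on
    the pooled ensemble.  Members with undefined moments (trivial
    solutions) are dropped from the reduction and counted.
    """
    per_member: list[dict[str, float]] = []
    s0s, tensors = [], {bd.name: [] for bd in bins}
    for sol in ensemble.solutions:
        ms = distribution_moments(sol)
        if ms is None:
            continue
        rec = _moment_record(ms)
        fr = bin_fractions(sol, bins)
        rec.update({f"f_{name}": v for name, v in fr.items()})
        rec.update({f"f_thick_{name}": v
                    for name, v in sub_bin_thick(sol, bins).items()})
        idx = _bin_index(sol, bins)
        for k, bd in enumerate(bins):
            sub = sol.select(idx == k)
            sub_ms = distribution_moments(sub)
            if sub_ms is not None:
                rec.update({f"{bd.name}_{key}": v for key, v
                            in _moment_record(sub_ms).items()})
                tensors[bd.name].append(_lab_tensor(sub))
        per_member.append(rec)
        s0s.append(sol.s0)

    if not per_member:
        return VoxelSummary(s0_med=0.0, stats={}, uncertainty={},
                            n_defined=0)

    keys = sorted(set().union(*per_member))
    stats, unc = {}, {}
    for key in keys:
        med, mad = ensemble_reduce([rec.get(key, np.nan)
                                    for rec in per_member])
        stats[key], unc[key] = med, mad

    bin_summaries = {}
    for bd in bins:
        ts = tensors[bd.name]
        tensor = np.median(np.stack(ts), axis=0) if ts else None
        rgb = None
        if tensor is not None:
            diag = np.diag(tensor)
            rgb = diag / diag.max()
        bin_summaries[bd.name] = BinSummary(
            fraction=stats.get(f"f_{bd.name}", 0.0),
            moments={k: stats[f"{bd.name}_{k}"] for k in
                     [f"e_{a}" for a in _AXES]
                     if f"{bd.name}_{k}" in stats},
            uncertainty={k: unc[f"{bd.name}_{k}"] for k in
                         [f"e_{a}" for a in _AXES]
                         if f"{bd.name}_{k}" in unc},
            mean_tensor=tensor, rgb=rgb)

    return VoxelSummary(
        s0_med=float(np.median(s0s)),
        stats={k: v for k, v in stats.items() if not k.startswith(
            tuple(f"{bd.name}_" for bd in bins))},
        uncertainty={k: v for k, v in unc.items() if not k.startswith(
            tuple(f"{bd.name}_" for bd in bins))},
        bins=bin_summaries,
        sub_bins={name: stats.get(f"f_thick_{name}", 0.0)
                  for name in THICK_SUB_BINS},
        n_defined=len(per_member))


def mixed_voxel_r2_separation(summary: VoxelSummary,
                              min_fraction: float = 0.30,
                              ) -> dict[str, bool]:
    """Classify a voxel as a resolvable thin+thick mixture.

    ``mixed``: both the thin and thick bins hold at least ``min_fraction``
    of the voxel's signal.  ``separated``: additionally, the two bins'
    median E[R2] differ by more than the sum of their MAD uncertainties.
    """
    thin = summary.bins.get("thin")
    thick = summary.bins.get("thick")
    if thin is None or thick is None or "e_r2" not in thin.moments \
            or "e_r2" not in thick.moments:
        return {"mixed": False, "separated": False}
    mixed = thin.fraction >= min_fraction and thick.fraction >= min_fraction
    gap = abs(thin.moments["e_r2"] - thick.moments["e_r2"])
    sep = mixed and gap > thin.uncertainty["e_r2"] + thick.uncertainty["e_r2"]
    return {"mixed": bool(mixed), "separated": bool(sep)}


def collate_summaries(summaries: Sequence[VoxelSummary],
                      s0_mask_fraction: float = 0.05) -> pd.DataFrame:
    """Long-format table of statistics over an S0-masked voxel collection.

    Keeps voxels whose median S0 exceeds ``s0_mask_fraction`` of the
    maximum median S0; one row per (voxel, statistic).
    """
    s0 = np.array([s.s0_med for s in summaries], dtype=float)
    rows = []
    if len(s0) and s0.max() > 0:
        thresh = s0_mask_fraction * s0.max()
        for v, summ in enumerate(summaries):
            if s0[v] <= thresh:
                continue
            for key, val in summ.stats.items():
                rows.append({"voxel": v, "statistic": key, "central": val,
                             "uncertainty": summ.uncertainty.get(key, np.nan),
                             "s0_norm": s0[v] / s0.max()})
    return pd.DataFrame(rows, columns=["voxel", "statistic", "central",
                                       "uncertainty", "s0_norm"])


class EnsembleSummarizer(TransformerMixin, BaseEstimator):
    """Transformer from solution ensembles to voxel summary tables.

    ``transform`` accepts a sequence of :class:`SolutionEnsemble` (e.g. the
    ``ensembles_`` of a fitted :class:`~rd5d.inversion.MonteCarloInverter`)
    and returns the long-format statistics table; the per-voxel
    :class:`VoxelSummary` objects are kept on ``summaries_``.
    """

    def __init__(self, bins: Sequence[BinDefinition] = DEFAULT_BINS,
                 s0_mask_fraction: float = 0.05):
        self.bins = bins
        self.s0_mask_fraction = s0_mask_fraction

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        self.summaries_ = [summarize_ensemble(ens, self.bins) for ens in X]
        return collate_summaries(self.summaries_, self.s0_mask_fraction)
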