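"""Acquisition schemes for 5D relaxation–diffusion encoding.

A scheme is an ordered table of per-measurement encoding variables: echo
time τE (s), b-tensor trace b (s·m⁻²), normalized b-tensor anisotropy
bΔ ∈ [−0.5, 1], and b-tensor orientation (Θ, Φ) (rad).  Protocols are
described compactly as :class:`ShapeBlock` lists — one block per b-tensor
shape, carrying its b-values, per-shell direction counts and echo times —
and expanded to a full point table with :func:`expand_protocol`.

Gradient direction sets are generated by seeded electrostatic-repulsion
descent with antipodal symmetry; the adequacy criterion is the pair energy,
not any particular published table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionPoint", "AcquisitionScheme", "ShapeBlock",
    "electrostatic_directions", "pair_energy", "expand_protocol",
    "read_scheme", "write_scheme", "preset_scheme",
]

_COLUMNS = ("tau_e", "b", "b_delta", "theta", "phi")


@dataclass(frozen=True)
class AcquisitionPoint:
    """One measurement's encoding variables (SI units, radians)."""

    tau_e: float
    b: float
    b_delta: float
    Theta: float
    Phi: float

    def __post_init__(self) -> None:
        if self.tau_e <= 0:
            raise ValueError(f"tau_e must be positive, got {self.tau_e}")
        if self.b < 0:
            raise ValueError(f"b must be non-negative, got {self.b}")
        if not -0.5 <= self.b_delta <= 1.0:
            raise ValueError(f"b_delta must lie in [-0.5, 1], got {self.b_delta}")
        if not 0 <= self.Theta <= np.pi:
            raise ValueError(f"Theta must lie in [0, pi], got {self.Theta}")


@dataclass
class AcquisitionScheme:
    """Ordered table of acquisition points, stored as parallel arrays."""

    tau_e: np.ndarray
    b: np.ndarray
    b_delta: np.ndarray
    Theta: np.ndarray
    Phi: np.ndarray
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        arrs = [np.atleast_1d(np.asarray(a, dtype=float)) for a in
                (self.tau_e, self.b, self.b_delta, self.Theta, self.Phi)]
        n = arrs[0].shape[0]
        if n == 0:
            raise ValueError("a scheme must contain at least one point")
        if any(a.shape != (n,) for a in arrs):
            raise ValueError("scheme columns must share one length")
        self.tau_e, self.b, self.b_delta, self.Theta, self.Phi = arrs
        if np.any(self.tau_e <= 0):
            raise ValueError("all tau_e must be positive")
        if np.any(self.b < 0):
            raise ValueError("all b must be non-negative")
        if np.any((self.b_delta < -0.5) | (self.b_delta > 1.0)):
            raise ValueError("all b_delta must lie in [-0.5, 1]")
        self.Phi = np.mod(self.Phi, 2 * np.pi)

    def __len__(self) -> int:
        return self.tau_e.shape[0]

    @property
    def points(self) -> list[AcquisitionPoint]:
        return [AcquisitionPoint(*vals) for vals in
                zip(self.tau_e, self.b, self.b_delta, self.Theta, self.Phi)]

    @classmethod
    def from_points(cls, points: Sequence[AcquisitionPoint],
                    label: str = "") -> "AcquisitionScheme":
        return cls(tau_e=np.array([p.tau_e for p in points]),
                   b=np.array([p.b for p in points]),
                   b_delta=np.array([p.b_delta for p in points]),
                   Theta=np.array([p.Theta for p in points]),
                   Phi=np.array([p.Phi for p in points]),
                   label=label)

    def select(self, idx) -> "AcquisitionScheme":
        return AcquisitionScheme(self.tau_e[idx], self.b[idx],
                                 self.b_delta[idx], self.Theta[idx],
                                 self.Phi[idx], label=self.label)


@dataclass
class ShapeBlock:
    """One b-tensor shape's shells: b-values, direction counts, echo times.

    When ``single_direction`` is set (the spherical-encoding convention,
    where orientation is irrelevant) every "direction" slot is the same
    fixed axis, so ``n_dirs_per_b`` counts plain repeats.
    """

    b_delta: float
    b_values: Sequence[float]
    n_dirs_per_b: Sequence[int]
    tau_e_list: Sequence[float]
    single_direction: bool = False

    def __post_init__(self) -> None:
        if len(self.b_values) != len(self.n_dirs_per_b):
            raise ValueError("b_values and n_dirs_per_b must have equal length")
        if any(n < 1 for n in self.n_dirs_per_b):
            raise ValueError("direction counts must be >= 1")
        if not -0.5 <= self.b_delta <= 1.0:
            raise ValueError("b_delta must lie in [-0.5, 1]")


# ---------------------------------------------------------------------------
# direction generation
# ---------------------------------------------------------------------------

def _sph_to_cart(theta, phi):
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], -1)


def _cart_to_sph(u):
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    theta = np.arccos(np.clip(u[..., 2], -1, 1))
    phi = np.mod(np.arctan2(u[..., 1], u[..., 0]), 2 * np.pi)
    return theta, phi


def pair_energy(dirs: np.ndarray) -> float:
    """Antipodally symmetric electrostatic energy of unit vectors (n, 3).

    E = Σ_{i<j} 1/|u_i − u_j| + 1/|u_i + u_j|.  Zero by convention for a
    single direction.
    """
    dirs = np.atleast_2d(dirs)
    n = dirs.shape[0]
    if n < 2:
        return 0.0
    diff = dirs[:, None, :] - dirs[None, :, :]
    summ = dirs[:, None, :] + dirs[None, :, :]
    iu = np.triu_indices(n, 1)
    dm = np.linalg.norm(diff, axis=-1)[iu]
    sm = np.linalg.norm(summ, axis=-1)[iu]
    # coincident or antipodal pairs carry infinite energy by definition
    with np.errstate(divide="ignore"):
        return float(np.sum(1.0 / dm) + np.sum(1.0 / sm))


def _repulsion_descent(u: np.ndarray, n_iter: int = 600) -> np.ndarray:
    """Projected gradient descent of the antipodal pair energy on the sphere."""
    n = u.shape[0]
    step = 0.05 / n
    e_prev = pair_energy(u)
    for _ in range(n_iter):
        diff = u[:, None, :] - u[None, :, :]
        summ = u[:, None, :] + u[None, :, :]
        dm = np.linalg.norm(diff, axis=-1)
        sm = np.linalg.norm(summ, axis=-1)
        np.fill_diagonal(dm, np.inf)
        np.fill_diagonal(sm, np.inf)
        grad = (-(diff / dm[..., None] ** 3).sum(1)
                - (summ / sm[..., None] ** 3).sum(1))
        grad -= (grad * u).sum(-1, keepdims=True) * u  # tangent projection
        trial = u - step * grad
        trial /= np.linalg.norm(trial, axis=-1, keepdims=True)
        e_new = pair_energy(trial)
        if e_new < e_prev:
            u, e_prev = trial, e_new
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-14:
                break
    return u


def electrostatic_directions(n: int, seed: int = 0,
                             n_restarts: int = 3) -> np.ndarray:
    """n unit directions minimising the antipodal electrostatic energy.

    Deterministic given ``seed``; returns spherical angles as an (n, 2)
    array of (θ, φ).  Best of ``n_restarts`` seeded random initialisations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if n == 1:
        return np.array([[0.0, 0.0]])
    best, best_e = None, np.inf
    for _ in range(n_restarts):
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        u = _repulsion_descent(u)
        e = pair_energy(u)
        if e < best_e:
            best, best_e = u, e
    theta, phi = _cart_to_sph(best)
    return np.stack([theta, phi], -1)


# ---------------------------------------------------------------------------
# protocol expansion
# ---------------------------------------------------------------------------

def expand_protocol(blocks: Sequence[ShapeBlock],
                    extra_blocks: Sequence[ShapeBlock] = (),
                    seed: int = 0, label: str = "") -> AcquisitionScheme:
    """Expand shape blocks into a full scheme.

    One point per (direction, b, bΔ, τE) combination.  Ordering: blocks in
    input order (extra blocks appended), then τE, then b, then direction.
    Each (block, b) shell gets its own electrostatic direction set.
    """
    rows = []
    for bi, block in enumerate(list(blocks) + list(extra_blocks)):
        shell_dirs = []
        for si, (bval, ndir) in enumerate(zip(block.b_values,
                                              block.n_dirs_per_b)):
            if block.single_direction:
                shell_dirs.append(np.zeros((ndir, 2)))
            else:
                shell_dirs.append(
                    electrostatic_directions(ndir, seed=seed * 10007 + bi * 101 + si))
        for tau_e in block.tau_e_list:
            for bval, dirs in zip(block.b_values, shell_dirs):
                for th, ph in dirs:
                    rows.append((tau_e, bval, block.b_delta, th, ph))
    arr = np.array(rows)
    return AcquisitionScheme(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3],
                             arr[:, 4], label=label)


# ---------------------------------------------------------------------------
# serialization — TSV with SI-unit header, or JSON with explicit units
# ---------------------------------------------------------------------------

def write_scheme(scheme: AcquisitionScheme, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "label": scheme.label,
            "units": {"tau_e": "s", "b": "s/m^2", "b_delta": "1",
                      "theta": "rad", "phi": "rad"},
            "points": [dict(zip(_COLUMNS, map(float, row)))
                       for row in zip(scheme.tau_e, scheme.b, scheme.b_delta,
                                      scheme.Theta, scheme.Phi)],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    lines = ["\t".join(_COLUMNS)]
    for row in zip(scheme.tau_e, scheme.b, scheme.b_delta, scheme.Theta,
                   scheme.Phi):
        lines.append("\t".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def _convert_units(cols: dict, header: list[str]) -> dict:
    # accepted header dialects: "b[s/mm^2]" (×1e6 to SI), angle "[deg]"
    for raw in header:
        name = raw.split("[")[0]
        if "[" not in raw:
            continue
        unit = raw[raw.index("[") + 1:raw.rindex("]")]
        if name == "b" and unit in ("s/mm^2", "s mm-2", "s/mm2"):
            cols["b"] = cols["b"] * 1e6
        elif name in ("theta", "phi") and unit == "deg":
            cols[name] = np.deg2rad(cols[name])
        elif name == "tau_e" and unit == "ms":
            cols["tau_e"] = cols["tau_e"] * 1e-3
    return cols


def read_scheme(path) -> AcquisitionScheme:
    """Read a scheme written by :func:`write_scheme` (TSV or JSON).

    TSV headers may carry unit tags, e.g. ``b[s/mm^2]`` (converted ×10⁶ to
    s·m⁻²), ``theta[deg]``/``phi[deg]``, ``tau_e[ms]``.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        pts = payload["points"]
        cols = {c: np.array([p[c] for p in pts], dtype=float)
                for c in _COLUMNS}
        return AcquisitionScheme(cols["tau_e"], cols["b"], cols["b_delta"],
                                 cols["theta"], cols["phi"],
                                 label=payload.get("label", ""))
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    names = [h.split("[")[0] for h in header]
    missing = set(_COLUMNS) - set(names)
    if missing:
        raise ValueError(f"scheme file {path} is missing column(s): "
                         f"{sorted(missing)}")
    cols = {name: [] for name in names}
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(names):
            raise ValueError(f"scheme file {path}, row {i}: expected "
                             f"{len(names)} fields, got {len(fields)}")
        try:
            for name, f in zip(names, fields):
                cols[name].append(float(f))
        except ValueError as err:
            raise ValueError(f"scheme file {path}, row {i}: {err}") from None
    cols = {k: np.array(v) for k, v in cols.items()}
    cols = _convert_units(cols, header)
    return AcquisitionScheme(cols["tau_e"], cols["b"], cols["b_delta"],
                             cols["theta"], cols["phi"], label=path.stem)


# ---------------------------------------------------------------------------
# preset protocols
# ---------------------------------------------------------------------------

def _full45_blocks():
    b4 = [0.1e9, 0.7e9, 1.4e9, 2.0e9]
    b6 = [0.1e9, 0.3e9, 0.7e9, 1.0e9, 1.4e9, 2.0e9]
    te3 = [0.080, 0.110, 0.150]
    blocks = [
        ShapeBlock(1.0, b4, [6, 10, 16, 40], te3),
        ShapeBlock(0.5, b4, [6, 10, 16, 32], te3),
        ShapeBlock(-0.5, b4, [6, 10, 16, 32], te3),
        ShapeBlock(0.0, b6, [6] * 6, te3, single_direction=True),
    ]
    extra = [ShapeBlock(1.0, b4, [6, 10, 16, 40], [0.060, 0.080])]
    return blocks, extra


def _short15_blocks():
    # compressed variant: 87% of points at two echo times
    b4 = [0.1e9, 0.7e9, 1.4e9, 2.0e9]
    b6 = [0.1e9, 0.3e9, 0.7e9, 1.0e9, 1.4e9, 2.0e9]
    te2 = [0.080, 0.150]
    blocks = [
        ShapeBlock(1.0, b4, [4, 6, 10, 22], te2),
        ShapeBlock(0.5, b4, [4, 6, 10, 14], te2),
        ShapeBlock(-0.5, b4, [4, 6, 10, 14], te2),
        ShapeBlock(0.0, b6, [2] * 6, te2, single_direction=True),
    ]
    extra = [ShapeBlock(1.0, b4, [4, 6, 10, 16], [0.110])]
    return blocks, extra


def _mini_blocks():
    # small scheme for fast tests; varies all five encoding variables
    te3 = [0.055, 0.095, 0.150]
    blocks = [
        ShapeBlock(1.0, [0.8e9, 2.0e9], [4, 6], te3),
        ShapeBlock(0.0, [0.1e9, 0.7e9, 1.4e9, 2.0e9], [1] * 4, te3,
                   single_direction=True),
        ShapeBlock(-0.5, [2.0e9], [3], te3),
    ]
    return blocks, []


def preset_scheme(name: str, seed: int = 0) -> AcquisitionScheme:
    """Built-in protocols.

    ``full45``: the exhaustive 852-point protocol — four b-tensor shapes
    (bΔ = 1, ±0.5, 0) over shells at b ≤ 2×10⁹ s·m⁻² and echo times 80/110/
    150 ms, plus a linear-encoding block at 60/80 ms.
    ``short15``: an abbreviated ~280-point variant concentrating 87% of
    points at two echo times (the published abbreviation's defining
    property; its exact shell table is not public, so this is a same-
    generator approximation).
    ``mini``: ≤64 points for fast tests.
    """
    builders = {"full45": _full45_blocks, "short15": _short15_blocks,
                "mini": _mini_blocks}
    if name not in builders:
        raise ValueError(f"unknown preset {name!r}; choose from "
                         f"{sorted(builders)}")
    blocks, extra = builders[name]()
    return expand_protocol(blocks, extra, seed=seed, label=name)
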